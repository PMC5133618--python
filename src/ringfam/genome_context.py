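"""Gene structure, collinearity and duplication-mode classification.

Gene models are read from GFF3; paralogy comes from a 12-column tabular
all-vs-all homology report.  Collinear blocks are chained by dynamic
programming over gene ranks, and each family gene is assigned exactly
one duplication mode with the precedence
``segmental_wgd > tandem > proximal > dispersed``.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from scipy import stats

__all__ = [
    "CollinearBlock",
    "DuplicationCall",
    "GeneModel",
    "HomologyHit",
    "chain_collinear_blocks",
    "classify_duplications",
    "parse_gene_models",
    "read_hit_table",
    "retention_enrichment",
    "top_k_hits",
]

BLAST12_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

MODES = ("segmental_wgd", "tandem", "proximal", "dispersed", "singleton")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    rank: int = -1  # index along chromosome by start; set by parse

    @property
    def intron_count(self) -> int:
        return len(self.exons) - 1


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    score: float
    evalue: float


@dataclass(frozen=True)
class CollinearBlock:
    chrom_a: str
    chrom_b: str
    anchors: tuple[tuple[str, str], ...]  # (gene_a, gene_b) pairs in chain order
    orientation: str  # "same" or "reversed"
    score: float

    def genes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.anchors:
            out.add(a)
            out.add(b)
        return out


@dataclass(frozen=True)
class DuplicationCall:
    gene_id: str
    mode: str


def parse_gene_models(gff3_path) -> list[GeneModel]:
    """One :class:`GeneModel` per gene from a GFF3 file.

    The longest mRNA (by summed exon length) represents each gene;
    exonless mRNAs become single-exon models with a warning.  Ranks are
    assigned per chromosome by ascending start.
    """
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        best_exons: tuple[tuple[int, int], ...] | None = None
        best_len = -1
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = sorted(
                (f.start, f.end) for f in db.children(mrna, featuretype="exon")
            )
            if not exons:
                warnings.warn(
                    f"mRNA {mrna.id} of gene {gene.id} has no exons; "
                    "using a single-exon model"
                )
                exons = [(mrna.start, mrna.end)]
            spliced = sum(e - s + 1 for s, e in exons)
            if spliced > best_len:
                best_len = spliced
                best_exons = tuple(exons)
        if best_exons is None:
            best_exons = ((gene.start, gene.end),)
        models.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                strand=gene.strand or ".",
                start=gene.start,
                end=gene.end,
                exons=best_exons,
            )
        )
    # rank per chromosome by start
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for m in models:
        by_chrom[m.chromosome].append(m)
    ranked: list[GeneModel] = []
    for chrom_models in by_chrom.values():
        chrom_models.sort(key=lambda m: (m.start, m.gene_id))
        for i, m in enumerate(chrom_models):
            ranked.append(
                GeneModel(m.gene_id, m.chromosome, m.strand, m.start, m.end, m.exons, i)
            )
    ranked.sort(key=lambda m: (m.chromosome, m.rank))
    return ranked


def read_hit_table(path) -> list[HomologyHit]:
    """Read 12-column tabular homology hits (BLAST outfmt-6 layout)."""
    df = pd.read_csv(path, sep="\t", names=BLAST12_COLUMNS, comment="#")
    return [
        HomologyHit(r.qseqid, r.sseqid, float(r.bitscore), float(r.evalue))
        for r in df.itertuples()
    ]


def top_k_hits(
    raw_hits: list[HomologyHit], k: int = 5, evalue_max: float = 1e-5
) -> list[HomologyHit]:
    """Per query keep the k best non-self hits passing the E-value cut.

    Ties at the k-th place are broken by lexicographically smaller
    subject id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    per_query: dict[str, list[HomologyHit]] = defaultdict(list)
    for h in raw_hits:
        if h.query_id == h.subject_id or h.evalue > evalue_max:
            continue
        per_query[h.query_id].append(h)
    kept: list[HomologyHit] = []
    for q in sorted(per_query):
        hits = sorted(per_query[q], key=lambda h: (-h.score, h.subject_id))
        kept.extend(hits[:k])
    return kept


def _chain_dp(
    anchors: list[tuple[int, int, float]], max_gap: int, reverse: bool
) -> list[list[int]]:
    """Greedy extraction of maximal-score DP chains over rank anchors.

    ``anchors`` are (q_rank, s_rank, score).  Chains must increase in
    q_rank and increase (or decrease when ``reverse``) in s_rank with
    rank gaps <= max_gap on both axes.  Returns chains as lists of
    anchor indices; anchors are consumed greedily best-chain-first.
    """
    order = sorted(range(len(anchors)), key=lambda i: (anchors[i][0], anchors[i][1]))
    available = set(order)
    chains: list[list[int]] = []
    while True:
        idxs = [i for i in order if i in available]
        if not idxs:
            break
        # chain value is (anchor count, summed score): length dominates so
        # one high-scoring stray anchor cannot mask a long block
        best_score: list[tuple[int, float]] = [(0, 0.0)] * len(idxs)
        back: list[int | None] = [None] * len(idxs)
        for a, i in enumerate(idxs):
            qi, si, wi = anchors[i]
            best_score[a] = (1, wi)
            for b in range(a):
                j = idxs[b]
                qj, sj, _ = anchors[j]
                dq = qi - qj
                ds = (sj - si) if reverse else (si - sj)
                if 0 < dq <= max_gap and 0 < ds <= max_gap:
                    cand = (best_score[b][0] + 1, best_score[b][1] + wi)
                    if cand > best_score[a]:
                        best_score[a] = cand
                        back[a] = b
        top = max(range(len(idxs)), key=lambda a: best_score[a])
        chain: list[int] = []
        cur: int | None = top
        while cur is not None:
            chain.append(idxs[cur])
            cur = back[cur]
        chain.reverse()
        if len(chain) < 2:
            break
        chains.append(chain)
        available -= set(chain)
    return chains


def chain_collinear_blocks(
    hits: list[HomologyHit],
    gene_models: list[GeneModel],
    max_gap_rank: int = 25,
    min_block_size: int = 5,
) -> list[CollinearBlock]:
    """Chain homology anchors into collinear blocks per chromosome pair.

    Both orientations are scanned; blocks with fewer than
    ``min_block_size`` anchors are dropped.  Hits involving genes absent
    from ``gene_models`` are ignored.
    """
    info = {m.gene_id: m for m in gene_models}
    pair_anchors: dict[tuple[str, str], dict[tuple[str, str], float]] = defaultdict(dict)
    for h in hits:
        a, b = info.get(h.query_id), info.get(h.subject_id)
        if a is None or b is None or a.gene_id == b.gene_id:
            continue
        # canonical orientation of the pair so reciprocal hits collapse
        if (a.chromosome, a.rank) > (b.chromosome, b.rank):
            a, b = b, a
        key = (a.chromosome, b.chromosome)
        pk = (a.gene_id, b.gene_id)
        pair_anchors[key][pk] = max(pair_anchors[key].get(pk, 0.0), h.score)

    blocks: list[CollinearBlock] = []
    for (ca, cb), amap in sorted(pair_anchors.items()):
        anchor_list = [
            (info[ga].rank, info[gb].rank, sc) for (ga, gb), sc in amap.items()
        ]
        names = list(amap.keys())
        for reverse in (False, True):
            for chain in _chain_dp(anchor_list, max_gap_rank, reverse):
                if len(chain) >= min_block_size:
                    blocks.append(
                        CollinearBlock(
                            chrom_a=ca,
                            chrom_b=cb,
                            anchors=tuple(names[i] for i in chain),
                            orientation="reversed" if reverse else "same",
                            score=sum(anchor_list[i][2] for i in chain),
                        )
                    )
    blocks.sort(key=lambda b: (-b.score, b.chrom_a, b.chrom_b))
    return blocks


def classify_duplications(
    hits: list[HomologyHit],
    gene_models: list[GeneModel],
    blocks: list[CollinearBlock],
    tandem_max_rank_gap: int = 1,
    proximal_max_rank_gap: int = 10,
    family: set[str] | None = None,
) -> list[DuplicationCall]:
    """One duplication mode per gene.

    Precedence: gene appears in a collinear block anchor -> segmental or
    whole-genome; else paralog at rank distance <= tandem gap on the
    same chromosome -> tandem; else within the proximal window ->
    proximal; else any paralog at all -> dispersed; else singleton.
    Genes on unplaced scaffolds never qualify for rank-based modes.
    """
    info = {m.gene_id: m for m in gene_models}
    genes = sorted(family) if family is not None else sorted(info)
    for g in genes:
        if g not in info:
            raise KeyError(f"gene {g!r} absent from gene models")

    in_block: set[str] = set()
    for b in blocks:
        in_block |= b.genes()

    partners: dict[str, set[str]] = defaultdict(set)
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        partners[h.query_id].add(h.subject_id)
        partners[h.subject_id].add(h.query_id)

    def is_unplaced(chrom: str) -> bool:
        return chrom.lower() in ("chrun", "un", "chrun.fa", "unknown")

    calls: list[DuplicationCall] = []
    for g in genes:
        gm = info[g]
        pset = {p for p in partners.get(g, ()) if p in info}
        if g in in_block:
            mode = "segmental_wgd"
        elif not pset:
            mode = "singleton"
        else:
            min_gap = None
            if not is_unplaced(gm.chromosome):
                same = [
                    info[p]
                    for p in pset
                    if info[p].chromosome == gm.chromosome
                    and not is_unplaced(info[p].chromosome)
                ]
                if same:
                    min_gap = min(abs(p.rank - gm.rank) for p in same)
            if min_gap is not None and min_gap <= tandem_max_rank_gap:
                mode = "tandem"
            elif min_gap is not None and min_gap <= proximal_max_rank_gap:
                mode = "proximal"
            else:
                mode = "dispersed"
        calls.append(DuplicationCall(g, mode))
    return calls


def pairwise_score_matrix(sequences: dict[str, str]) -> pd.DataFrame:
    """All-vs-all local alignment scores (BLOSUM62, gap open 11 /
    extend 1) for download-free synthetic fixtures.

    Real all-vs-all search output in the 12-column tabular format is the
    first-class input; this scorer only backs small in-repo runs and the
    sequence-similarity side of the expression association test.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    ids = list(sequences)
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i:]:
            score = float(aligner.score(sequences[a], sequences[b]))
            mat.loc[a, b] = mat.loc[b, a] = score
    return mat


def scores_to_hits(
    scores: pd.DataFrame, min_score: float, evalue: float = 1e-10
) -> list[HomologyHit]:
    """Threshold a raw score matrix into non-self homology hits."""
    hits: list[HomologyHit] = []
    for q in scores.index:
        for s in scores.columns:
            if q != s and scores.loc[q, s] >= min_score:
                hits.append(HomologyHit(q, s, float(scores.loc[q, s]), evalue))
    return hits


def retention_enrichment(
    family_modes: dict[str, int], genome_modes: dict[str, int]
) -> pd.DataFrame:
    """Per-mode Fisher's exact enrichment of the family against the
    genome background, Bonferroni-corrected over the modes tested.

    ``genome_modes`` counts include the family.  Zero-margin tables get
    p = 1.0 and are flagged.
    """
    tested = sorted(set(family_modes) | set(genome_modes))
    n_tests = len(tested)
    rows = []
    fam_total = sum(family_modes.values())
    gen_total = sum(genome_modes.values())
    for mode in tested:
        a = family_modes.get(mode, 0)                 # family, this mode
        b = fam_total - a                             # family, other modes
        c = genome_modes.get(mode, 0) - a             # background, this mode
        d = (gen_total - fam_total) - c               # background, other
        if min(a + b, c + d, a + c, b + d) < 0:
            raise ValueError("genome counts must include the family counts")
        degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
        if degenerate:
            odds, p = float("nan"), 1.0
        else:
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "mode": mode,
                "family": a,
                "background": c,
                "odds_ratio": odds,
                "p_value": p,
                "p_bonferroni": min(1.0, p * n_tests),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("mode")
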