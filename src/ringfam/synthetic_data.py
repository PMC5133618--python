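"""Seeded synthetic inputs with known ground truth for every stage.

Every generator is a pure function of (parameters, seed): the same call
produces byte-identical files.  Planted truth covers each generated
entity so downstream recovery can be asserted exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression_profiles import welch_de_table
from .ring_grammar import AMINO_ACIDS, MotifGrammar, ProteinRecord, scan_ring_h2

__all__ = [
    "SyntheticTruth",
    "gen_bundle",
    "gen_expression",
    "gen_genome",
    "gen_proteome",
    "write_fasta",
    "write_gff3",
]

_NON_LIGAND = AMINO_ACIDS.replace("C", "").replace("H", "").replace("W", "").replace("P", "")


@dataclass
class SyntheticTruth:
    """Ground-truth labels for one generated dataset."""

    seed: int
    proteins: dict = field(default_factory=dict)
    genes: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "proteins": self.proteins,
                    "genes": self.genes,
                    "expression": self.expression,
                },
                fh,
                indent=1,
                sort_keys=True,
            )


def _rand_seq(rng: np.random.Generator, n: int, alphabet: str = AMINO_ACIDS) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def _build_motif(
    rng: np.random.Generator, subtype: str, spacer_dist: tuple[int, int]
) -> tuple[str, list[int]]:
    """Assemble a compliant motif string and its 0-based ligand offsets."""
    lo, hi = spacer_dist
    n1 = int(rng.integers(lo, hi + 1))  # C2 -> proline region
    n2 = int(rng.integers(lo, hi + 1))  # post-W region before C7
    if subtype == "PxC":
        mid = _rand_seq(rng, n1, _NON_LIGAND) + "P" + _rand_seq(rng, 1, _NON_LIGAND)
    else:
        mid = _rand_seq(rng, n1, _NON_LIGAND) + "P"
    parts = [
        "C", _rand_seq(rng, 2, _NON_LIGAND),
        "C", mid,
        "C", _rand_seq(rng, 1, _NON_LIGAND),
        "H", _rand_seq(rng, 2, _NON_LIGAND),
        "H", _rand_seq(rng, 2, _NON_LIGAND),
        "C", _rand_seq(rng, 3, _NON_LIGAND), "W", _rand_seq(rng, n2, _NON_LIGAND),
        "C", _rand_seq(rng, 2, _NON_LIGAND),
        "C",
    ]
    motif = "".join(parts)
    offsets = []
    pos = 0
    for p in parts:
        if p in "CH" and len(p) == 1:
            offsets.append(pos)
        pos += len(p)
    # the lone W spacer piece is not a ligand; drop its offset if captured
    ligand_offsets = [o for o in offsets if motif[o] in "CH"]
    # exactly 8 ligands: 3C, 2H, 3C -- the W part above is multi-char safe
    assert len(ligand_offsets) == 8, ligand_offsets
    return motif, ligand_offsets


def _break_motif(
    rng: np.random.Generator, motif: str, offsets: list[int], violation: str
) -> str:
    """Apply exactly one grammar violation to a compliant motif."""
    s = list(motif)
    if violation == "ligand":
        s[offsets[int(rng.integers(0, 8))]] = "A"
    elif violation == "spacer":
        # stretch the first fixed gap (C1..C2) from 2 to 4 residues
        return motif[: offsets[0] + 1] + "AA" + motif[offsets[0] + 1 :]
    elif violation == "missing_w":
        w_off = offsets[5] + 4  # 0-based: three residues after the sixth ligand
        assert motif[w_off] == "W"
        s[w_off] = "A"
    elif violation == "no_proline":
        c3 = offsets[2]  # 0-based; P sits one or two positions earlier
        if motif[c3 - 1] == "P":
            s[c3 - 1] = "A"
        if motif[c3 - 2] == "P":
            s[c3 - 2] = "A"
    else:
        raise ValueError(f"unknown violation {violation!r}")
    return "".join(s)


def gen_proteome(
    n_atl: int,
    n_btl: int,
    n_decoys: int,
    spacer_dist: tuple[int, int] = (4, 30),
    seed: int = 0,
    grammar: MotifGrammar | None = None,
    max_resample: int = 200,
) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Proteins with planted RING-H2 motifs plus single-violation decoys.

    ATL records carry a PxC-grammar motif, BTL records a PC motif (their
    truth entries are flagged ``has_bzf``), and each decoy violates
    exactly one constraint.  Records are rejection-sampled until the
    scanner finds exactly the planted motif (or nothing, for decoys), so
    the truth labels are exact by construction.
    """
    if min(n_atl, n_btl, n_decoys) < 0:
        raise ValueError("counts must be >= 0")
    if grammar is None:
        grammar = MotifGrammar()
    lo, hi = spacer_dist
    glo, ghi = grammar.spacer_ranges[1]
    if lo + 1 < glo or hi + 2 > ghi:
        raise ValueError(
            f"spacer_dist {spacer_dist} falls outside the grammar's variable "
            f"gap ({glo}, {ghi})"
        )
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    truth = SyntheticTruth(seed=seed)
    violations = ["ligand", "spacer", "missing_w", "no_proline"]

    plan = (
        [("atl", "PxC")] * n_atl + [("btl", "PC")] * n_btl + [("decoy", None)] * n_decoys
    )
    for i, (kind, subtype) in enumerate(plan):
        pid = f"{kind.upper()}{i + 1:04d}"
        for attempt in range(max_resample):
            sub = subtype or ("PxC" if rng.integers(0, 2) else "PC")
            motif, offsets = _build_motif(rng, sub, spacer_dist)
            violation = None
            if kind == "decoy":
                violation = violations[i % len(violations)]
                motif = _break_motif(rng, motif, offsets, violation)
            nterm = _rand_seq(rng, int(rng.integers(20, 120)))
            cterm = _rand_seq(rng, int(rng.integers(10, 80)))
            seq = nterm + motif + cterm
            rec = ProteinRecord(pid, seq, description=kind)
            matches = scan_ring_h2(rec, grammar)
            if kind == "decoy":
                if not matches:
                    truth.proteins[pid] = {"kind": kind, "violation": violation}
                    break
            else:
                planted = tuple(len(nterm) + o + 1 for o in offsets)
                if (
                    len(matches) == 1
                    and matches[0].ligand_positions == planted
                    and matches[0].subtype == sub
                ):
                    truth.proteins[pid] = {
                        "kind": kind,
                        "subtype": sub,
                        "ligand_positions": list(planted),
                        "has_bzf": kind == "btl",
                    }
                    break
        else:
            raise RuntimeError(f"could not generate a clean record for {pid}")
        records.append(rec)
    return records, truth


_DEFAULT_INTRON_DIST = {0: 0.5, 1: 0.15, 2: 0.12, 3: 0.1, 4: 0.07, 5: 0.06}


def _draw_introns(rng: np.random.Generator, intron_dist) -> int:
    if intron_dist is None:
        intron_dist = _DEFAULT_INTRON_DIST
    if isinstance(intron_dist, int):
        return intron_dist
    ks = sorted(intron_dist)
    ps = np.array([intron_dist[k] for k in ks], dtype=float)
    ps /= ps.sum()
    return int(rng.choice(ks, p=ps))


def gen_genome(
    n_genes: int,
    n_wgd_pairs: int,
    n_tandem: int,
    n_proximal: int,
    n_dispersed: int,
    intron_dist=None,
    seed: int = 0,
    n_chromosomes: int = 8,
    min_block_size: int = 5,
    proximal_max_rank_gap: int = 10,
    n_noise_hits: int | None = None,
) -> tuple[list[dict], pd.DataFrame, SyntheticTruth]:
    """Gene models plus a homology-hit table with planted paralog modes.

    Whole-genome/segmental pairs are embedded in collinear runs of at
    least ``min_block_size`` anchors, tandem pairs are rank-adjacent,
    proximal pairs sit within the proximal rank window, dispersed pairs
    span chromosomes.  Noise hits join background genes on chromosome
    pairs unused by blocks, capped so they can never chain into a
    spurious block; those genes are truthfully dispersed.

    Returns (gene dicts for :func:`write_gff3`, 12-column hit table,
    truth).
    """
    needed = 2 * (n_wgd_pairs + n_tandem + n_proximal + n_dispersed)
    if needed > n_genes:
        raise ValueError("planted pairs need more genes than n_genes provides")
    if 0 < n_wgd_pairs < min_block_size:
        raise ValueError(f"n_wgd_pairs must be 0 or >= min_block_size ({min_block_size})")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed)

    per_chrom = [n_genes // n_chromosomes] * n_chromosomes
    for i in range(n_genes % n_chromosomes):
        per_chrom[i] += 1
    chroms = [f"chr{i + 1}" for i in range(n_chromosomes)]
    slots: dict[str, list[str | None]] = {c: [None] * n for c, n in zip(chroms, per_chrom)}

    gene_counter = [0]

    def new_gene(chrom: str, rank: int) -> str:
        gene_counter[0] += 1
        gid = f"g{gene_counter[0]:04d}"
        slots[chrom][rank] = gid
        return gid

    pair_hits: list[tuple[str, str]] = []
    modes: dict[str, str] = {}
    block_chrom_pairs: set[tuple[str, str]] = set()
    # anchors planted outside blocks, per chromosome pair; kept below
    # min_block_size so they can never chain into a spurious block
    anchor_budget: dict[tuple[str, str], int] = {}

    def budget_ok(c1: str, c2: str) -> bool:
        key = tuple(sorted((c1, c2)))
        return key not in block_chrom_pairs and anchor_budget.get(key, 0) < min_block_size - 1

    def budget_take(c1: str, c2: str) -> None:
        key = tuple(sorted((c1, c2)))
        anchor_budget[key] = anchor_budget.get(key, 0) + 1

    # --- WGD blocks ------------------------------------------------------
    remaining = n_wgd_pairs
    while remaining > 0:
        size = min_block_size if remaining >= 2 * min_block_size else remaining
        if remaining - size == 0 or remaining - size >= min_block_size:
            pass
        else:
            size = remaining
        placed = False
        for _ in range(500):
            ca, cb = rng.choice(n_chromosomes, size=2, replace=False)
            ca, cb = chroms[ca], chroms[cb]
            if len(slots[ca]) < size or len(slots[cb]) < size:
                continue
            sa = int(rng.integers(0, len(slots[ca]) - size + 1))
            sb = int(rng.integers(0, len(slots[cb]) - size + 1))
            if any(slots[ca][sa + i] for i in range(size)) or any(
                slots[cb][sb + i] for i in range(size)
            ):
                continue
            if ca == cb and not (sa + size <= sb or sb + size <= sa):
                continue
            for i in range(size):
                ga = new_gene(ca, sa + i)
                gb = new_gene(cb, sb + i)
                pair_hits.append((ga, gb))
                modes[ga] = modes[gb] = "segmental_wgd"
            block_chrom_pairs.add(tuple(sorted((ca, cb))))
            placed = True
            break
        if not placed:
            raise ValueError("could not place WGD blocks; layout infeasible")
        remaining -= size

    def place_same_chrom(gap_lo: int, gap_hi: int, mode: str) -> None:
        for _ in range(500):
            c = chroms[int(rng.integers(0, n_chromosomes))]
            hi = min(gap_hi, len(slots[c]) - 1)
            if hi < gap_lo:
                continue
            gap = int(rng.integers(gap_lo, hi + 1))
            r = int(rng.integers(0, len(slots[c]) - gap))
            if slots[c][r] is None and slots[c][r + gap] is None and budget_ok(c, c):
                ga = new_gene(c, r)
                gb = new_gene(c, r + gap)
                pair_hits.append((ga, gb))
                modes[ga] = modes[gb] = mode
                budget_take(c, c)
                return
        raise ValueError(f"could not place a {mode} pair; layout infeasible")

    for _ in range(n_tandem):
        place_same_chrom(1, 1, "tandem")
    for _ in range(n_proximal):
        place_same_chrom(2, proximal_max_rank_gap, "proximal")

    def free_slot(exclude_chrom: str | None = None) -> tuple[str, int]:
        for _ in range(1000):
            c = chroms[int(rng.integers(0, n_chromosomes))]
            if c == exclude_chrom or not slots[c]:
                continue
            r = int(rng.integers(0, len(slots[c])))
            if slots[c][r] is None:
                return c, r
        raise ValueError("no free slots left; layout infeasible")

    for _ in range(n_dispersed):
        for _ in range(1000):
            ca, ra = free_slot()
            cb, rb = free_slot(exclude_chrom=ca)
            if budget_ok(ca, cb):
                break
        else:
            raise ValueError("could not place a dispersed pair; layout infeasible")
        ga = new_gene(ca, ra)
        gb = new_gene(cb, rb)
        pair_hits.append((ga, gb))
        modes[ga] = modes[gb] = "dispersed"
        budget_take(ca, cb)

    # fill remaining slots with background singletons
    background: list[tuple[str, str]] = []
    for c in chroms:
        for r, g in enumerate(slots[c]):
            if g is None:
                gid = new_gene(c, r)
                modes[gid] = "singleton"
                background.append((c, gid))

    # --- noise hits between background genes -----------------------------
    if n_noise_hits is None:
        n_noise_hits = n_genes // 10
    noise_pairs: list[tuple[str, str]] = []
    rng.shuffle(background)
    pool = list(background)
    for _ in range(n_noise_hits):
        found = None
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                (c1, g1), (c2, g2) = pool[i], pool[j]
                if c1 == c2 or not budget_ok(c1, c2):
                    continue
                found = (i, j, c1, g1, c2, g2)
                break
            if found:
                break
        if not found:
            break
        i, j, c1, g1, c2, g2 = found
        budget_take(c1, c2)
        noise_pairs.append((g1, g2))
        modes[g1] = modes[g2] = "dispersed"
        pool = [p for k, p in enumerate(pool) if k not in (i, j)]

    # --- gene coordinates and structures ---------------------------------
    genes: list[dict] = []
    for c in chroms:
        pos = 1
        for r, gid in enumerate(slots[c]):
            length = int(rng.integers(600, 4000))
            start = pos
            end = start + length - 1
            pos = end + int(rng.integers(2000, 8000))
            n_introns = _draw_introns(rng, intron_dist)
            exons = _split_exons(rng, start, end, n_introns)
            genes.append(
                {
                    "gene_id": gid,
                    "chromosome": c,
                    "strand": "+" if rng.integers(0, 2) else "-",
                    "start": start,
                    "end": end,
                    "exons": exons,
                }
            )
            truth.genes[gid] = {
                "mode": modes[gid],
                "chromosome": c,
                "rank": r,
                "intron_count": n_introns,
            }

    rows = []
    for qa, qb in pair_hits + noise_pairs:
        score = float(rng.integers(200, 500))
        for q, s in ((qa, qb), (qb, qa)):
            rows.append(
                [q, s, 90.0, 300, 10, 1, 1, 300, 1, 300, 1e-50, score]
            )
    hit_df = pd.DataFrame(
        rows,
        columns=[
            "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore",
        ],
    )
    return genes, hit_df, truth


def _split_exons(
    rng: np.random.Generator, start: int, end: int, n_introns: int
) -> list[tuple[int, int]]:
    min_exon, min_intron = 30, 20
    length = end - start + 1
    n_exons = n_introns + 1
    base = n_exons * min_exon + n_introns * min_intron
    if n_exons == 1 or length < base:
        return [(start, end)]
    extra = length - base
    shares = rng.multinomial(extra, np.ones(2 * n_exons - 1) / (2 * n_exons - 1))
    lengths = []
    for i in range(2 * n_exons - 1):
        minimum = min_exon if i % 2 == 0 else min_intron
        lengths.append(minimum + int(shares[i]))
    exons = []
    pos = start
    for i, ln in enumerate(lengths):
        if i % 2 == 0:
            exons.append((pos, pos + ln - 1))
        pos += ln
    # absorb rounding into the final exon so the model spans [start, end]
    exons[-1] = (exons[-1][0], end)
    return exons


def gen_expression(
    n_genes: int,
    n_samples: int,
    n_clusters: int,
    n_contrasts: int,
    effect_lfc: float,
    noise_sd: float,
    seed: int = 0,
    n_responsive: int | None = None,
    reps_per_group: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Atlas matrix with planted gene clusters plus per-contrast DE
    tables with planted responsive genes.

    Responsive genes receive a mean shift of +/- ``effect_lfc`` in two
    contrasts (one when only one contrast exists); every other
    gene-contrast combination is a true null, so its p-value is uniform.
    DE statistics come from the Welch-t stand-in on simulated groups.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if n_clusters > n_genes or n_clusters < 1:
        raise ValueError("need 1 <= n_clusters <= n_genes")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed)
    genes = [f"gene{i + 1:04d}" for i in range(n_genes)]
    samples = [f"sample{j + 1:03d}" for j in range(n_samples)]

    labels = np.array([i % n_clusters for i in range(n_genes)])
    centers = rng.normal(0.0, 2.0, size=(n_clusters, n_samples))
    atlas = centers[labels] + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    expr = pd.DataFrame(atlas, index=genes, columns=samples)

    if n_responsive is None:
        n_responsive = max(1, n_genes // 10)
    responsive = sorted(rng.choice(n_genes, size=n_responsive, replace=False).tolist())
    resp_set = {genes[i] for i in responsive}
    per_gene_contrasts: dict[str, list[int]] = {}
    k_hit = min(2, n_contrasts)
    for gi in responsive:
        hit = sorted(rng.choice(n_contrasts, size=k_hit, replace=False).tolist())
        per_gene_contrasts[genes[gi]] = hit

    de_frames = []
    for c in range(n_contrasts):
        cname = f"contrast{c + 1}"
        shift = np.zeros(n_genes)
        for gi in responsive:
            if c in per_gene_contrasts[genes[gi]]:
                shift[gi] = effect_lfc * (1 if rng.integers(0, 2) else -1)
        ctrl = rng.normal(0.0, noise_sd, size=(n_genes, reps_per_group))
        treat = shift[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, reps_per_group))
        cols = [f"{cname}_{g}{r}" for g in ("t", "c") for r in range(reps_per_group)]
        mat = pd.DataFrame(np.hstack([treat, ctrl]), index=genes, columns=cols)
        groups = pd.Series(
            ["treat"] * reps_per_group + ["ctrl"] * reps_per_group, index=cols
        )
        de = welch_de_table(mat, groups, [("treat", "ctrl")])
        de["contrast"] = cname
        de_frames.append(de)
    de_table = pd.concat(de_frames, ignore_index=True)

    truth.expression = {
        "cluster_labels": {g: int(l) for g, l in zip(genes, labels)},
        "responsive": sorted(resp_set),
        "responsive_contrasts": {
            g: [f"contrast{c + 1}" for c in cs] for g, cs in per_gene_contrasts.items()
        },
        "effect_lfc": effect_lfc,
    }
    return expr, de_table, truth


def write_fasta(records: list[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            fh.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_gff3(genes: list[dict], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g["chromosome"], g["start"])):
            gid = g["gene_id"]
            fh.write(
                f"{g['chromosome']}\tsynthetic\tgene\t{g['start']}\t{g['end']}\t.\t"
                f"{g['strand']}\t.\tID={gid}\n"
            )
            mid = f"{gid}.t1"
            fh.write(
                f"{g['chromosome']}\tsynthetic\tmRNA\t{g['start']}\t{g['end']}\t.\t"
                f"{g['strand']}\t.\tID={mid};Parent={gid}\n"
            )
            for k, (s, e) in enumerate(g["exons"], 1):
                fh.write(
                    f"{g['chromosome']}\tsynthetic\texon\t{s}\t{e}\t.\t"
                    f"{g['strand']}\t.\tID={mid}.exon{k};Parent={mid}\n"
                )


def gen_bundle(
    outdir,
    seed: int = 0,
    n_atl: int = 30,
    n_btl: int = 10,
    n_decoys: int = 20,
    n_genes: int = 200,
    n_wgd_pairs: int = 10,
    n_tandem: int = 4,
    n_proximal: int = 1,
    n_dispersed: int = 6,
    n_expr_genes: int = 100,
    n_samples: int = 24,
    n_clusters: int = 3,
    n_contrasts: int = 4,
    effect_lfc: float = 2.0,
    noise_sd: float = 0.1,
) -> Path:
    """Emit a complete synthetic input directory: proteome.fasta,
    genome.gff3, hits.tsv, domains.tsv, expr.tsv, de.tsv, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=3)

    records, ptruth = gen_proteome(n_atl, n_btl, n_decoys, seed=int(sub_seeds[0]))
    write_fasta(records, outdir / "proteome.fasta")
    with open(outdir / "domains.tsv", "w") as fh:
        fh.write("protein_id\tdomain_name\tstart\tend\tscore\n")
        for pid, info in ptruth.proteins.items():
            if info.get("has_bzf"):
                fh.write(f"{pid}\tzf-RING_3\t5\t45\t25.0\n")

    genes, hits, gtruth = gen_genome(
        n_genes, n_wgd_pairs, n_tandem, n_proximal, n_dispersed, seed=int(sub_seeds[1])
    )
    write_gff3(genes, outdir / "genome.gff3")
    hits.to_csv(outdir / "hits.tsv", sep="\t", header=False, index=False)

    expr, de, etruth = gen_expression(
        n_expr_genes, n_samples, n_clusters, n_contrasts, effect_lfc, noise_sd,
        seed=int(sub_seeds[2]),
    )
    expr.to_csv(outdir / "expr.tsv", sep="\t", index_label="gene")
    de.to_csv(outdir / "de.tsv", sep="\t", index=False)

    truth = SyntheticTruth(seed=seed)
    truth.proteins = ptruth.proteins
    truth.genes = gtruth.genes
    truth.expression = etruth.expression
    truth.to_json(outdir / "truth.json")
    return outdir
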