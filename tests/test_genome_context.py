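import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from ringfam.genome_context import (
    CollinearBlock,
    GeneModel,
    HomologyHit,
    chain_collinear_blocks,
    classify_duplications,
    parse_gene_models,
    read_hit_table,
    retention_enrichment,
    top_k_hits,
    _chain_dp,
)


def fisher_two_sided_oracle(a, b, c, d) -> float:
    """Exact two-sided Fisher p by hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed that of the observed table.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(k):
        return Fraction(comb(r1, k) * comb(r2, c1 - k), denom)

    p_obs = prob(a)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = prob(k)
        if pk <= p_obs:
            total += pk
    return float(total)


def exhaustive_best_chain(anchors, max_gap, reverse):
    """Maximum (length, score) chain by enumeration over all subsets."""
    n = len(anchors)
    best = (0, 0.0)
    order = sorted(range(n), key=lambda i: (anchors[i][0], anchors[i][1]))
    for r in range(1, n + 1):
        for combo in itertools.combinations(order, r):
            ok = True
            for x, y in zip(combo, combo[1:]):
                qx, sx, _ = anchors[x]
                qy, sy, _ = anchors[y]
                dq = qy - qx
                ds = (sx - sy) if reverse else (sy - sx)
                if not (0 < dq <= max_gap and 0 < ds <= max_gap):
                    ok = False
                    break
            if ok:
                cand = (r, sum(anchors[i][2] for i in combo))
                best = max(best, cand)
    return best


def make_models(layout):
    """layout: list of (gene_id, chrom, rank)."""
    models = []
    for gid, chrom, rank in layout:
        start = rank * 1000 + 1
        models.append(
            GeneModel(gid, chrom, "+", start, start + 500, ((start, start + 500),), rank)
        )
    return models


def hit(q, s, score=100.0, evalue=1e-20):
    return HomologyHit(q, s, score, evalue)


class TestParseGeneModels:
    def test_intron_counts_and_ranks(self, tmp_path):
        gff = tmp_path / "t.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1\t500\t.\t+\t.\tID=gA\n"
            "chr1\tsrc\tmRNA\t1\t500\t.\t+\t.\tID=gA.t1;Parent=gA\n"
            "chr1\tsrc\texon\t1\t100\t.\t+\t.\tID=gA.e1;Parent=gA.t1\n"
            "chr1\tsrc\texon\t201\t300\t.\t+\t.\tID=gA.e2;Parent=gA.t1\n"
            "chr1\tsrc\texon\t401\t500\t.\t+\t.\tID=gA.e3;Parent=gA.t1\n"
            "chr1\tsrc\tgene\t1000\t1400\t.\t-\t.\tID=gB\n"
            "chr1\tsrc\tmRNA\t1000\t1400\t.\t-\t.\tID=gB.t1;Parent=gB\n"
            "chr1\tsrc\texon\t1000\t1400\t.\t-\t.\tID=gB.e1;Parent=gB.t1\n"
        )
        models = {m.gene_id: m for m in parse_gene_models(gff)}
        assert models["gA"].intron_count == 2
        assert models["gB"].intron_count == 0
        assert models["gA"].rank == 0 and models["gB"].rank == 1

    def test_longest_mrna_wins(self, tmp_path):
        gff = tmp_path / "t.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1\t900\t.\t+\t.\tID=g\n"
            "chr1\tsrc\tmRNA\t1\t900\t.\t+\t.\tID=g.t1;Parent=g\n"
            "chr1\tsrc\texon\t1\t100\t.\t+\t.\tID=e1;Parent=g.t1\n"
            "chr1\tsrc\tmRNA\t1\t900\t.\t+\t.\tID=g.t2;Parent=g\n"
            "chr1\tsrc\texon\t1\t400\t.\t+\t.\tID=e2;Parent=g.t2\n"
            "chr1\tsrc\texon\t600\t900\t.\t+\t.\tID=e3;Parent=g.t2\n"
        )
        (model,) = parse_gene_models(gff)
        assert model.intron_count == 1  # g.t2: longer spliced form

    def test_exonless_mrna_single_exon(self, tmp_path):
        gff = tmp_path / "t.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1\t300\t.\t+\t.\tID=g\n"
            "chr1\tsrc\tmRNA\t1\t300\t.\t+\t.\tID=g.t1;Parent=g\n"
        )
        with pytest.warns(UserWarning):
            (model,) = parse_gene_models(gff)
        assert model.exons == ((1, 300),)


class TestTopKHits:
    def test_keeps_best_five(self):
        hits = [hit("q", f"s{i}", score=10.0 * i) for i in range(1, 8)]
        kept = top_k_hits(hits, k=5)
        assert len(kept) == 5
        assert {h.subject_id for h in kept} == {"s3", "s4", "s5", "s6", "s7"}

    def test_self_hit_only(self):
        assert top_k_hits([hit("q", "q")]) == []

    def test_tie_break_lexicographic(self):
        hits = [hit("q", "sB", 50.0), hit("q", "sA", 50.0), hit("q", "sC", 99.0)]
        kept = top_k_hits(hits, k=2)
        assert [h.subject_id for h in kept] == ["sC", "sA"]

    def test_evalue_filter(self):
        hits = [hit("q", "s1", evalue=1e-3), hit("q", "s2", evalue=1e-9)]
        kept = top_k_hits(hits, evalue_max=1e-5)
        assert [h.subject_id for h in kept] == ["s2"]

    def test_read_hit_table_roundtrip(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q1\ts1\t90.0\t100\t5\t1\t1\t100\t1\t100\t1e-30\t222.0\n")
        (h,) = read_hit_table(p)
        assert h.query_id == "q1" and h.score == 222.0
        assert h.evalue == pytest.approx(1e-30)


class TestChaining:
    def test_planted_forward_block(self):
        layout = [(f"a{i}", "chr1", i) for i in range(6)] + [
            (f"b{i}", "chr2", i) for i in range(6)
        ]
        models = make_models(layout)
        hits = [hit(f"a{i}", f"b{i}") for i in range(6)]
        blocks = chain_collinear_blocks(hits, models, min_block_size=5)
        assert len(blocks) == 1
        assert len(blocks[0].anchors) == 6
        assert blocks[0].orientation == "same"

    def test_reversed_block(self):
        layout = [(f"a{i}", "chr1", i) for i in range(5)] + [
            (f"b{i}", "chr2", i) for i in range(5)
        ]
        models = make_models(layout)
        hits = [hit(f"a{i}", f"b{4 - i}") for i in range(5)]
        blocks = chain_collinear_blocks(hits, models, min_block_size=5)
        assert len(blocks) == 1
        assert blocks[0].orientation == "reversed"

    def test_sparse_anchors_no_block(self):
        layout = [("a0", "chr1", 0), ("a9", "chr1", 9), ("b0", "chr2", 0), ("b9", "chr2", 9)]
        models = make_models(layout)
        hits = [hit("a0", "b0"), hit("a9", "b9")]
        assert chain_collinear_blocks(hits, models, min_block_size=5) == []

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("reverse", [False, True])
    def test_dp_equals_exhaustive(self, seed, reverse):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        anchors = [
            (int(rng.integers(0, 15)), int(rng.integers(0, 15)), float(rng.integers(1, 9)))
            for _ in range(n)
        ]
        # deduplicate coordinates to respect anchor-map semantics
        anchors = list({(q, s): (q, s, w) for q, s, w in anchors}.values())
        chains = _chain_dp(anchors, max_gap=5, reverse=reverse)
        got = max(
            ((len(c), sum(anchors[i][2] for i in c)) for c in chains),
            default=(1, max(w for _, _, w in anchors)),
        )
        want = exhaustive_best_chain(anchors, 5, reverse)
        assert got == want


class TestClassification:
    def test_tandem_pair(self):
        models = make_models([("g1", "chr1", 0), ("g2", "chr1", 1)])
        calls = classify_duplications([hit("g1", "g2")], models, [])
        assert {c.mode for c in calls} == {"tandem"}

    def test_proximal_pair(self):
        models = make_models([("g1", "chr1", 0), ("g2", "chr1", 5)])
        calls = classify_duplications(
            [hit("g1", "g2")], models, [], proximal_max_rank_gap=10
        )
        assert {c.mode for c in calls} == {"proximal"}

    def test_dispersed_and_singleton(self):
        models = make_models([("g1", "chr1", 0), ("g2", "chr2", 0), ("g3", "chr3", 0)])
        calls = {c.gene_id: c.mode for c in classify_duplications([hit("g1", "g2")], models, [])}
        assert calls == {"g1": "dispersed", "g2": "dispersed", "g3": "singleton"}

    def test_block_precedence(self):
        models = make_models([("g1", "chr1", 0), ("g2", "chr1", 1)])
        block = CollinearBlock("chr1", "chr1", (("g1", "g2"),), "same", 100.0)
        calls = classify_duplications([hit("g1", "g2")], models, [block])
        assert {c.mode for c in calls} == {"segmental_wgd"}

    def test_unplaced_gene_dispersed_not_tandem(self):
        models = make_models([("g1", "chrUn", 0), ("g2", "chrUn", 1)])
        calls = classify_duplications([hit("g1", "g2")], models, [])
        assert {c.mode for c in calls} == {"dispersed"}

    def test_missing_gene_error(self):
        models = make_models([("g1", "chr1", 0)])
        with pytest.raises(KeyError):
            classify_duplications([], models, [], family={"ghost"})

    def test_order_and_rename_invariance(self):
        layout = [("g1", "chr1", 0), ("g2", "chr1", 1), ("g3", "chr2", 0), ("g4", "chr2", 4)]
        models = make_models(layout)
        hits = [hit("g1", "g2"), hit("g3", "g4")]
        base = {c.gene_id: c.mode for c in classify_duplications(hits, models, [])}
        # permuted input order
        perm = {c.gene_id: c.mode for c in classify_duplications(hits[::-1], models[::-1], [])}
        assert base == perm
        # renamed ids
        rename = {"g1": "x9", "g2": "x2", "g3": "x7", "g4": "x1"}
        models2 = make_models([(rename[g], c, r) for g, c, r in layout])
        hits2 = [hit(rename["g1"], rename["g2"]), hit(rename["g3"], rename["g4"])]
        renamed = {c.gene_id: c.mode for c in classify_duplications(hits2, models2, [])}
        assert renamed == {rename[g]: m for g, m in base.items()}


class TestEnrichment:
    def test_matches_hypergeometric_oracle(self):
        fam = {"tandem": 8, "dispersed": 2}
        genome = {"tandem": 18, "dispersed": 82}
        df = retention_enrichment(fam, genome)
        p = df.loc["tandem", "p_value"]
        assert p == pytest.approx(fisher_two_sided_oracle(8, 2, 10, 80), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_tables_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(rng.integers(0, 50)) for _ in range(4))
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            return
        fam = {"m": a, "other": b}
        genome = {"m": a + c, "other": b + d}
        df = retention_enrichment(fam, genome)
        assert df.loc["m", "p_value"] == pytest.approx(
            fisher_two_sided_oracle(a, b, c, d), abs=1e-12
        )

    def test_proportional_counts_null(self):
        fam = {"tandem": 5, "dispersed": 5}
        genome = {"tandem": 50, "dispersed": 50}
        df = retention_enrichment(fam, genome)
        assert df.loc["tandem", "odds_ratio"] == pytest.approx(1.0)
        assert df.loc["tandem", "p_value"] == pytest.approx(1.0)

    def test_bonferroni_capped(self):
        fam = {"a": 3, "b": 3, "c": 3, "d": 3}
        genome = {"a": 30, "b": 30, "c": 30, "d": 30}
        df = retention_enrichment(fam, genome)
        assert (df["p_bonferroni"] <= 1.0).all()
        near = df["p_value"] * 4
        assert (df["p_bonferroni"] == near.clip(upper=1.0)).all()

    def test_zero_margin_flagged(self):
        df = retention_enrichment({"m": 0, "o": 5}, {"m": 0, "o": 50})
        assert bool(df.loc["m", "degenerate"]) is True
        assert df.loc["m", "p_value"] == 1.0
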