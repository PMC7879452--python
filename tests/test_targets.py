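"""Cis window, trans correlation and hypergeometric enrichment, with oracles."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncrecur import de as de_mod
from lncrecur.de import NormalizedExpression
from lncrecur.targets import (
    cis_targets,
    correlate_pair,
    format_pvalue,
    overrepresentation_test,
    trans_targets,
)
from lncrecur.types import TranscriptRecord, ValidationError


def _rec(tid, start, end, chrom="chr1", biotype="unclassified"):
    return TranscriptRecord(tid, f"g_{tid}", chrom, "+", start, end, end - start + 1, biotype)


def _expr(frame: pd.DataFrame) -> NormalizedExpression:
    return NormalizedExpression(
        values=frame.astype(float),
        pseudocount=1.0,
        libsize=pd.Series(1.0, index=frame.columns),
    )


class TestCisWindow:
    def test_gene_at_48kb_is_cis_with_correct_distance(self):
        lnc = _rec("L", 10_000, 12_000)
        gene = _rec("G", 60_000, 61_000, biotype="protein_coding")
        out = cis_targets([lnc], [gene])
        assert len(out) == 1
        assert out.iloc[0]["distance_bp"] == 48_000

    def test_gene_beyond_window_not_emitted(self):
        lnc = _rec("L", 10_000, 12_000)
        gene = _rec("G", 115_001, 116_000)
        assert cis_targets([lnc], [gene]).empty  # distance 103,001

    def test_boundary_distance_exactly_window_included(self):
        lnc = _rec("L", 10_000, 12_000)
        gene = _rec("G", 112_000, 113_000)
        out = cis_targets([lnc], [gene])  # gap exactly 100,000
        assert len(out) == 1
        assert out.iloc[0]["distance_bp"] == 100_000

    def test_overlapping_gene_has_distance_zero(self):
        lnc = _rec("L", 10_000, 12_000)
        gene = _rec("G", 11_500, 30_000)
        out = cis_targets([lnc], [gene])
        assert out.iloc[0]["distance_bp"] == 0

    def test_different_chromosome_never_cis(self):
        lnc = _rec("L", 10_000, 12_000, chrom="chr1")
        gene = _rec("G", 10_000, 12_000, chrom="chr2")
        assert cis_targets([lnc], [gene]).empty

    def test_negative_window_rejected(self):
        with pytest.raises(ValidationError):
            cis_targets([], [], window_bp=-1)

    def test_matches_brute_force_all_pairs_scan(self):
        """1,000 random loci: the interval-tree search equals an O(n^2)
        gap-distance scan exactly."""
        rng = np.random.default_rng(17)
        chroms = ["c1", "c2", "c3"]
        lncs, genes = [], []
        for i in range(400):
            start = int(rng.integers(1, 5_000_000))
            lncs.append(_rec(f"L{i}", start, start + int(rng.integers(200, 5000)),
                             chrom=chroms[int(rng.integers(3))]))
        for i in range(600):
            start = int(rng.integers(1, 5_000_000))
            genes.append(_rec(f"G{i}", start, start + int(rng.integers(1000, 50000)),
                              chrom=chroms[int(rng.integers(3))]))
        got = cis_targets(lncs, genes, 100_000)
        got_set = {(r.lnc_id, r.gene_id): r.distance_bp for r in got.itertuples()}
        expected = {}
        for l in lncs:
            for g in genes:
                if l.chrom != g.chrom:
                    continue
                if g.start > l.end:
                    dist = g.start - l.end
                elif l.start > g.end:
                    dist = l.start - g.end
                else:
                    dist = 0
                if dist <= 100_000:
                    expected[(l.transcript_id, g.transcript_id)] = dist
        assert got_set == expected


class TestTransCorrelation:
    def test_perfect_linearity_emitted(self):
        frame = pd.DataFrame(
            {"s1": [1, 2], "s2": [2, 4], "s3": [3, 6], "s4": [4, 8]},
            index=["L", "G"],
        )
        out = trans_targets(_expr(frame), ["L"], ["G"])
        assert len(out) == 1
        assert out.iloc[0]["r"] == pytest.approx(1.0)

    def test_r_below_threshold_not_emitted(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = 0.94 * x + np.sqrt(1 - 0.94**2) * rng.normal(size=30)
        frame = pd.DataFrame([x, y], index=["L", "G"],
                             columns=[f"s{i}" for i in range(30)])
        out = trans_targets(_expr(frame), ["L"], ["G"], r_min=0.95)
        r, _ = correlate_pair(_expr(frame), "L", "G")
        if abs(r) <= 0.95:  # true for this seed
            assert out.empty

    def test_matches_covariance_formula_oracle(self):
        """Random 20-sample vectors: r equals the raw sum formula to 1e-12."""
        rng = np.random.default_rng(7)
        frame = pd.DataFrame(
            rng.normal(size=(10, 20)),
            index=[f"t{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(20)],
        )
        expr = _expr(frame)
        for i in range(5):
            for j in range(5, 10):
                r, _ = correlate_pair(expr, f"t{i}", f"t{j}")
                x, y = frame.iloc[i].to_numpy(), frame.iloc[j].to_numpy()
                n = len(x)
                num = (x * y).sum() - n * x.mean() * y.mean()
                den = math.sqrt(
                    ((x**2).sum() - n * x.mean() ** 2)
                    * ((y**2).sum() - n * y.mean() ** 2)
                )
                assert r == pytest.approx(num / den, abs=1e-12)

    def test_correlate_pair_is_symmetric(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(rng.normal(size=(2, 15)), index=["a", "b"],
                             columns=[f"s{i}" for i in range(15)])
        expr = _expr(frame)
        assert correlate_pair(expr, "a", "b") == correlate_pair(expr, "b", "a")

    def test_anticorrelated_pair(self):
        frame = pd.DataFrame({"s1": [1, -1], "s2": [2, -2], "s3": [5, -5]},
                             index=["a", "b"])
        r, _ = correlate_pair(_expr(frame), "a", "b")
        assert r == pytest.approx(-1.0)

    def test_identical_vectors_underflow_pvalue(self):
        frame = pd.DataFrame(
            np.vstack([np.arange(30), np.arange(30)]).astype(float),
            index=["a", "b"], columns=[f"s{i}" for i in range(30)],
        )
        r, p = correlate_pair(_expr(frame), "a", "b")
        assert r == pytest.approx(1.0)
        assert p < 2.2e-16
        assert format_pvalue(p) == "<2.2e-16"

    def test_zero_r_at_n3_gives_p_one(self):
        frame = pd.DataFrame({"s1": [0, 1], "s2": [1, 1 + 0.0], "s3": [2, 1]},
                             index=["a", "b"])
        # y orthogonal to x: r = 0 -> t = 0 -> p = 1
        frame.loc["b"] = [0.0, 1.0, 0.0]
        r, p = correlate_pair(_expr(frame), "a", "b")
        assert r == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_variance_vector_skipped_with_warning(self):
        frame = pd.DataFrame({"s1": [1, 5], "s2": [2, 5], "s3": [3, 5]},
                             index=["L", "G"])
        with pytest.warns(UserWarning, match="zero-variance"):
            out = trans_targets(_expr(frame), ["L"], ["G"])
        assert out.empty

    def test_planted_trans_pairs_recovered(self, default_cohort, default_expr):
        """>= 90% of planted trans-true pairs pass the strict 0.95 rule."""
        _, cohort, truth = default_cohort
        coding = {t.transcript_id for t in cohort.annotation if t.biotype == "protein_coding"}
        out = trans_targets(default_expr, set(truth.trans_true["lnc_id"]), coding)
        emitted = set(zip(out["lnc_id"], out["gene_id"]))
        planted = set(zip(truth.trans_true["lnc_id"], truth.trans_true["gene_id"]))
        assert len(emitted & planted) / len(planted) >= 0.9


def hypergeom_oracle(M, K, N, k):
    """Exact upper tail P(X >= k) via Fractions over math.comb."""
    total = Fraction(0)
    for i in range(k, min(K, N) + 1):
        total += Fraction(math.comb(K, i) * math.comb(M - K, N - i), math.comb(M, N))
    return float(total)


class TestOverrepresentation:
    def test_extreme_enrichment_closed_form(self):
        universe = {f"g{i}" for i in range(20)}
        selected = {f"g{i}" for i in range(5)}
        sets = {"S": selected}
        out = overrepresentation_test(selected, sets, universe)
        assert out.iloc[0]["p"] == pytest.approx(1 / math.comb(20, 5), rel=1e-9)

    def test_disjoint_set_has_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        out = overrepresentation_test(
            {"g0", "g1"}, {"S": {"g10", "g11"}}, universe
        )
        assert out.iloc[0]["n_hits"] == 0
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_expected_proportion_has_large_p(self):
        # hits exactly proportional: 5/50 selected from a set of 10/100
        universe = {f"g{i}" for i in range(100)}
        selected = {f"g{i}" for i in range(50)}
        gene_set = {f"g{i}" for i in range(45, 55)}  # 5 hits of 10
        out = overrepresentation_test(selected, {"S": gene_set}, universe)
        assert out.iloc[0]["n_hits"] == 5
        assert out.iloc[0]["p"] > 0.5

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            overrepresentation_test(set(), {"S": {"a"}}, set())

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.data())
    def test_matches_exact_combinatorial_oracle(self, data):
        """scipy's upper tail equals Fraction-exact summation to 1e-12
        for populations up to 200."""
        M = data.draw(st.integers(min_value=5, max_value=200))
        K = data.draw(st.integers(min_value=0, max_value=M))
        N = data.draw(st.integers(min_value=1, max_value=M))
        universe = {f"g{i}" for i in range(M)}
        members = {f"g{i}" for i in range(K)}
        rng_sel = {f"g{i}" for i in range(M - N, M)}
        out = overrepresentation_test(rng_sel, {"S": members}, universe)
        k = out.iloc[0]["n_hits"]
        assert out.iloc[0]["p"] == pytest.approx(hypergeom_oracle(M, K, N, k), abs=1e-12)
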