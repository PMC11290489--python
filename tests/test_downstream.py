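"""Expression ratios, clustering, coupling enrichment, RCP statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rampscreen.downstream import (
    binarize_and_cluster,
    binarize_barr,
    coupling_enrichment,
    exact_rxc_test,
    expression_ratio_test,
    expression_ratios,
    molboolean_compare,
    molboolean_summarize,
    pct_interacting_per_context,
)
from rampscreen.errors import ValidationError


def _expr(rows):
    return pd.DataFrame(rows, columns=["gene_id", "context_id", "ntpm"])


def _ann(rows):
    return pd.DataFrame(rows, columns=["gpcr_id", "ramp_id", "annotation"])


class TestExpressionRatios:
    def test_ratio_rule_and_ntpm_gate(self):
        expr = _expr(
            [
                ("G1", "c1", 10.0),
                ("RAMP1", "c1", 5.0),
                ("G1", "c2", 10.0),
                ("RAMP1", "c2", 0.9),
            ]
        )
        ann = _ann([("G1", "RAMP1", "yes")])
        out = expression_ratios(expr, ann, "RAMP1")
        assert len(out) == 1  # c2 dropped: RAMP below 1 nTPM
        assert out.iloc[0]["ratio"] == pytest.approx(2.0)

    def test_inconclusive_excluded(self):
        expr = _expr([("G1", "c1", 10.0), ("RAMP1", "c1", 5.0)])
        ann = _ann([("G1", "RAMP1", "inconclusive")])
        assert expression_ratios(expr, ann, "RAMP1").empty

    def test_shifted_interactors_detected(self, rng):
        rows = [("RAMP1", f"c{j}", 10.0) for j in range(10)]
        ann_rows = []
        for i in range(60):
            yes = i < 30
            ann_rows.append((f"G{i}", "RAMP1", "yes" if yes else "no"))
            for j in range(10):
                base = rng.lognormal(2.0 + (1.5 if yes else 0.0), 0.5)
                rows.append((f"G{i}", f"c{j}", base))
        out = expression_ratio_test(_expr(rows), _ann(ann_rows))
        assert out.iloc[0]["p_value"] < 0.005
        assert out.iloc[0]["median_ratio_yes"] > out.iloc[0]["median_ratio_no"]

    def test_null_is_calibrated(self, rng):
        """Identically drawn yes/no ratios give a roughly uniform p-value."""
        pvals = []
        for rep in range(50):
            rows = [("RAMP1", f"c{j}", 10.0) for j in range(4)]
            ann_rows = []
            for i in range(30):
                ann_rows.append((f"G{i}", "RAMP1", "yes" if i < 15 else "no"))
                for j in range(4):
                    rows.append((f"G{i}", f"c{j}", rng.lognormal(2.0, 0.5)))
            out = expression_ratio_test(_expr(rows), _ann(ann_rows))
            pvals.append(out.iloc[0]["p_value"])
        assert 0.0 <= np.mean(np.array(pvals) < 0.05) <= 0.16


class TestBinarizeAndCluster:
    def test_strict_ntpm_cutoff(self):
        expr = _expr(
            [("A", "c1", 1.0), ("A", "c2", 1.01), ("B", "c1", 3.0), ("B", "c2", 0.0)]
        )
        binary, log2m, order = binarize_and_cluster(expr)
        assert not binary.loc["A", "c1"]
        assert binary.loc["A", "c2"]
        assert log2m.loc["A", "c1"] == 0.0
        assert log2m.loc["B", "c1"] == pytest.approx(np.log2(3.0))

    def test_identical_profiles_merge_first(self):
        rows = []
        for ctx in range(4):
            rows += [("A", f"c{ctx}", 4.0), ("B", f"c{ctx}", 4.0), ("C", f"c{ctx}", 400.0)]
        _, log2m, order = binarize_and_cluster(_expr(rows))
        pos = {g: i for i, g in enumerate(order)}
        assert abs(pos["A"] - pos["B"]) == 1  # identical pair adjacent

    def test_all_zero_rejected(self):
        rows = [("A", "c1", 0.0), ("A", "c2", 0.0), ("B", "c1", 0.0), ("B", "c2", 0.0)]
        with pytest.raises(ValidationError):
            binarize_and_cluster(_expr(rows))

    def test_leaf_order_stable_under_row_permutation(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(6)]
        rows = [(g, f"c{j}", float(rng.lognormal(1.5, 1))) for g in genes for j in range(5)]
        expr = _expr(rows)
        _, _, order1 = binarize_and_cluster(expr)
        shuffled = expr.sample(frac=1.0, random_state=1).reset_index(drop=True)
        _, _, order2 = binarize_and_cluster(shuffled)
        assert order1 == order2 or order1 == order2[::-1]


class TestPctInteractingPerContext:
    def test_two_thirds_one_third(self):
        expr = _expr(
            [("RAMP1", "c1", 5.0)]
            + [(f"G{i}", "c1", 10.0) for i in range(3)]
        )
        ann = _ann([("G0", "RAMP1", "yes"), ("G1", "RAMP1", "yes"), ("G2", "RAMP1", "no")])
        out = pct_interacting_per_context(expr, ann)
        row = out.iloc[0]
        assert row["pct_yes"] == pytest.approx(200 / 3)
        assert row["pct_no"] == pytest.approx(100 / 3)
        assert row["pct_yes"] + row["pct_no"] == pytest.approx(100.0)

    def test_context_absent_when_ramp_not_expressed(self):
        expr = _expr([("RAMP1", "c1", 0.5), ("G0", "c1", 10.0)])
        ann = _ann([("G0", "RAMP1", "yes")])
        assert pct_interacting_per_context(expr, ann).empty


def fisher_p_oracle(a, b, c, d):
    """Hypergeometric enumeration with math.comb only."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = math.comb(n, r1)
    p_obs = math.comb(c1, a) * math.comb(n - c1, r1 - a) / denom
    total = 0.0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        p = math.comb(c1, k) * math.comb(n - c1, r1 - k) / denom
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


class TestCouplingEnrichment:
    def _tables(self, members, interactors, gpcrs):
        coupling = []
        for g in gpcrs:
            if g in members:
                coupling.append((g, "Gs", "primary", np.nan))
            else:
                coupling.append((g, "Gq/11", "primary", np.nan))
        coupling = pd.DataFrame(
            coupling, columns=["gpcr_id", "transducer", "tier", "log_emax_over_ec50"]
        )
        ann = _ann([(g, "RAMP1", "yes" if g in interactors else "no") for g in gpcrs])
        return coupling, ann

    def test_balanced_table_null(self):
        gpcrs = [f"g{i}" for i in range(40)]
        members = set(gpcrs[:10]) | set(gpcrs[20:30])
        interactors = set(gpcrs[:20])
        coupling, ann = self._tables(members, interactors, gpcrs)
        out = coupling_enrichment(coupling, ann).set_index("comparison")
        row = out.loc["primary_Gs"]
        assert row["odds_ratio"] == pytest.approx(1.0, abs=1e-6)
        assert row["p_value"] == pytest.approx(1.0)

    def test_example_table_against_enumeration(self):
        assert float(stats.fisher_exact([[8, 2], [1, 5]])[1]) == pytest.approx(
            fisher_p_oracle(8, 2, 1, 5)
        )
        assert fisher_p_oracle(8, 2, 1, 5) == pytest.approx(0.0350, abs=5e-4)

    def test_barr_binarization(self):
        assert binarize_barr(0.0) is False
        assert binarize_barr(0.1) is True

    def test_exact_rxc_matches_fisher_on_2x2(self, rng):
        for _ in range(25):
            tab = rng.integers(0, 8, size=(2, 2))
            if tab.sum() == 0 or (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
                continue
            p_scipy = float(stats.fisher_exact(tab)[1])
            assert exact_rxc_test(tab) == pytest.approx(p_scipy, abs=1e-9)

    def test_exact_rxc_on_2x3(self):
        tab = np.array([[3, 1, 4], [1, 5, 0]])
        p = exact_rxc_test(tab)
        assert 0.0 < p <= 1.0
        # oracle: direct enumeration over the first row only (margins fix the rest)
        r1, r2 = tab.sum(axis=1)
        cols = tab.sum(axis=0)
        n = tab.sum()
        def prob(t):
            num = sum(math.lgamma(x + 1) for x in (*tab.sum(axis=1), *cols))
            den = math.lgamma(n + 1) + sum(math.lgamma(x + 1) for row in t for x in row)
            return math.exp(num - den)
        p_obs = prob(tab)
        total = 0.0
        for a in range(min(r1, cols[0]) + 1):
            for b in range(min(r1 - a, cols[1]) + 1):
                c = r1 - a - b
                if c < 0 or c > cols[2]:
                    continue
                bottom = [cols[0] - a, cols[1] - b, cols[2] - c]
                if any(x < 0 for x in bottom):
                    continue
                t = [[a, b, c], bottom]
                if prob(t) <= p_obs * (1 + 1e-9):
                    total += prob(t)
        assert p == pytest.approx(total, abs=1e-9)


class TestMolBoolean:
    def _rcp(self):
        return pd.DataFrame(
            [
                dict(image_id="i1", stain_condition="pair", nuclei=30, rcp_gpcr=300, rcp_ramp=150, rcp_overlap=60),
                dict(image_id="b1", stain_condition="blank", nuclei=10, rcp_gpcr=20, rcp_ramp=20, rcp_overlap=20),
            ]
        )

    def test_net_per_cell_arithmetic(self):
        out = molboolean_summarize(self._rcp())
        row = out.iloc[0]
        # 300/30 = 10 per cell, blank 2 per cell -> net 8
        assert row["net_rcp_gpcr"] == pytest.approx(8.0)
        assert row["net_rcp_ramp"] == pytest.approx(3.0)
        assert row["net_rcp_overlap"] == pytest.approx(0.0)

    def test_pct_overlap(self):
        rcp = pd.DataFrame(
            [
                dict(image_id="i1", stain_condition="pair", nuclei=10, rcp_gpcr=500, rcp_ramp=300, rcp_overlap=200),
                dict(image_id="b1", stain_condition="blank", nuclei=10, rcp_gpcr=0, rcp_ramp=0, rcp_overlap=0),
            ]
        )
        out = molboolean_summarize(rcp)
        assert out.iloc[0]["pct_overlap"] == pytest.approx(20.0)

    def test_blank_exceeding_signal_clamps(self):
        rcp = pd.DataFrame(
            [
                dict(image_id="i1", stain_condition="pair", nuclei=10, rcp_gpcr=5, rcp_ramp=5, rcp_overlap=5),
                dict(image_id="b1", stain_condition="blank", nuclei=1, rcp_gpcr=10, rcp_ramp=10, rcp_overlap=10),
            ]
        )
        out = molboolean_summarize(rcp)
        assert (out[["net_rcp_gpcr", "net_rcp_ramp", "net_rcp_overlap"]] >= 0).all().all()

    def test_missing_blank_rejected(self):
        rcp = self._rcp()
        with pytest.raises(ValidationError, match="blank"):
            molboolean_summarize(rcp[rcp["stain_condition"] != "blank"])

    def test_control_vs_halved_condition(self, rng):
        rows = []
        for cond, rate in (("ctrl", 3.0), ("same", 3.0), ("halved", 1.0)):
            for i in range(30):
                cells = 30
                rows.append(
                    dict(
                        image_id=f"{cond}_{i}",
                        stain_condition=cond,
                        nuclei=cells,
                        rcp_gpcr=int(rng.poisson(4.0 * cells)),
                        rcp_ramp=int(rng.poisson(4.0 * cells)),
                        rcp_overlap=int(rng.poisson(rate * cells)),
                    )
                )
        rows.append(dict(image_id="b", stain_condition="blank", nuclei=10, rcp_gpcr=0, rcp_ramp=0, rcp_overlap=0))
        out = molboolean_compare(molboolean_summarize(pd.DataFrame(rows)), "ctrl").set_index("stain_condition")
        assert out.loc["halved", "significant"]
        assert not out.loc["same", "significant"]
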