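"""Dimer dataset selection, geometric-mean regression, explainability."""

import numpy as np
import pandas as pd
import pytest

from ppiseq.mass_action import (
    build_dimer_dataset,
    classify_explained,
    explainability_logistic,
    fit_mass_action,
)

ENVS = [f"E{i}" for i in range(1, 10)]


def _matrices(rows: dict, calls: dict):
    f = pd.DataFrame.from_dict(rows, orient="index", columns=ENVS)
    c = pd.DataFrame.from_dict(calls, orient="index", columns=ENVS).astype(bool)
    return f, c


class TestBuildDimerDataset:
    def _base(self):
        good = np.linspace(0.2, 0.9, 9)
        rows = {"A:A": good, "B:B": good, "C:C": good}
        calls = {k: [True] * 9 for k in rows}
        return rows, calls

    def test_too_few_environments_excluded(self):
        rows, calls = self._base()
        ab = np.full(9, np.nan)
        ab[:3] = 0.5  # quantified in only three environments
        rows["A:B"] = ab
        calls["A:B"] = [True] * 9
        f, c = _matrices(rows, calls)
        assert build_dimer_dataset(f, c) == []

    def test_never_positive_excluded(self):
        rows, calls = self._base()
        rows["A:B"] = np.linspace(0.1, 0.5, 9)
        calls["A:B"] = [False] * 9
        f, c = _matrices(rows, calls)
        assert build_dimer_dataset(f, c) == []

    def test_constructed_fixture_exact_selection(self):
        rows, calls = self._base()
        # 6 heterodimer candidates; exactly 2 pass all filters
        rows["A:B"] = np.linspace(0.2, 0.6, 9)               # pass
        calls["A:B"] = [True] + [False] * 8
        rows["A:C"] = np.r_[np.full(6, np.nan), 0.4, 0.5, 0.6]  # only 3 envs
        calls["A:C"] = [True] * 9
        rows["B:C"] = np.linspace(0.1, 0.3, 9)               # pass
        calls["B:C"] = [False] * 8 + [True]
        rows["A:D"] = np.linspace(0.2, 0.6, 9)               # D has no homodimer
        calls["A:D"] = [True] * 9
        rows["B:D"] = np.linspace(0.2, 0.6, 9)
        calls["B:D"] = [True] * 9
        rows["C:D"] = np.linspace(0.2, 0.6, 9)
        calls["C:D"] = [True] * 9
        f, c = _matrices(rows, calls)
        kept = {r.pair_id for r in build_dimer_dataset(f, c)}
        assert kept == {"A:B", "B:C"}

    def test_orientations_pooled(self):
        rows, calls = self._base()
        rows["A:B"] = np.r_[np.linspace(0.2, 0.5, 5), np.full(4, np.nan)]
        calls["A:B"] = [True] * 9
        rows["B:A"] = np.r_[np.full(5, np.nan), np.linspace(0.2, 0.5, 4)]
        calls["B:A"] = [False] * 9
        f, c = _matrices(rows, calls)
        recs = build_dimer_dataset(f, c)
        assert len(recs) == 1 and len(recs[0].s_ab) == 9


class TestFitMassAction:
    def test_exact_construction(self):
        s_aa = np.linspace(0.2, 0.9, 9)
        s_bb = np.linspace(0.4, 0.8, 9)
        s_ab = np.sqrt(s_aa * s_bb)
        fit = fit_mass_action(s_ab, s_aa, s_bb)
        assert fit.slope == pytest.approx(1.0, abs=1e-8)
        assert fit.intercept == pytest.approx(0.0, abs=1e-8)
        assert fit.slope_p < 1e-6

    def test_constant_response_insignificant_slope(self, rng):
        s_aa = rng.uniform(0.2, 0.9, 9)
        s_bb = rng.uniform(0.2, 0.9, 9)
        fit = fit_mass_action(np.full(9, 0.5), s_aa, s_bb)
        assert fit.slope_p > 0.05

    def test_too_few_environments(self):
        with pytest.raises(ValueError):
            fit_mass_action([0.1] * 3, [0.1] * 3, [0.1] * 3)

    def test_beta_recovery_on_synthetic_pairs(self, rng):
        # median slope over 500 noisy pairs within 10% of truth
        betas = []
        for _ in range(500):
            beta0 = rng.uniform(0.5, 1.5)
            s_aa = rng.uniform(0.1, 0.9, 9)
            s_bb = rng.uniform(0.1, 0.9, 9)
            s_ab = beta0 * np.sqrt(s_aa * s_bb) + rng.normal(0, 0.02, 9)
            betas.append(fit_mass_action(s_ab, s_aa, s_bb).slope / beta0)
        assert abs(np.median(betas) - 1.0) < 0.10


class TestClassifyExplained:
    def test_single_perfect_fit_explained(self):
        s_aa = np.linspace(0.2, 0.9, 9)
        fit = fit_mass_action(np.sqrt(s_aa * s_aa) * 0.9, s_aa, s_aa, pair_id="A:B")
        out = classify_explained([fit])
        assert out.loc["A:B", "explained"]

    def test_significant_intercept_blocks_explained(self):
        s_aa = np.linspace(0.2, 0.9, 9)
        fit = fit_mass_action(0.9 * s_aa + 0.3, s_aa, s_aa, pair_id="A:B")
        out = classify_explained([fit])
        assert out.loc["A:B", "intercept_p"] < 0.05
        assert not out.loc["A:B", "explained"]

    def test_fdr_monotone(self, rng):
        fits = []
        for i in range(40):
            s_aa = rng.uniform(0.1, 0.9, 9)
            s_bb = rng.uniform(0.1, 0.9, 9)
            noise = 0.02 if i < 20 else 0.5
            s_ab = np.sqrt(s_aa * s_bb) + rng.normal(0, noise, 9)
            fits.append(fit_mass_action(s_ab, s_aa, s_bb, pair_id=f"p{i}"))
        out = classify_explained(fits)
        # loosening the FDR threshold never removes an explained pair
        strict = set(out.index[(out["slope_q"] < 0.01) & (out["intercept_p"] > 0.05)])
        loose = set(out.index[(out["slope_q"] < 0.10) & (out["intercept_p"] > 0.05)])
        assert strict <= loose

    def test_explained_fraction_recovery(self, rng):
        # 50% of pairs follow mass action; recovered fraction within 15 points
        fits = []
        n = 200
        for i in range(n):
            s_aa = rng.uniform(0.1, 0.9, 9)
            s_bb = rng.uniform(0.1, 0.9, 9)
            if i < n // 2:
                s_ab = rng.uniform(0.8, 1.2) * np.sqrt(s_aa * s_bb) + rng.normal(0, 0.05, 9)
            else:
                s_ab = rng.uniform(0.1, 0.7, 9)  # decoupled from the homodimers
            fits.append(fit_mass_action(s_ab, s_aa, s_bb, pair_id=f"p{i}"))
        out = classify_explained(fits)
        assert abs(out["explained"].mean() - 0.5) < 0.15


class TestExplainabilityLogistic:
    @staticmethod
    def _dimers(rng, n=60):
        from ppiseq.mass_action import DimerRecord

        recs, explained = [], {}
        for i in range(n):
            a, b = f"P{2 * i}", f"P{2 * i + 1}"
            recs.append(
                DimerRecord(
                    pair_id=f"{a}:{b}", protein_a=a, protein_b=b,
                    s_ab=np.zeros(4), s_aa=np.zeros(4), s_bb=np.zeros(4),
                    environments=tuple("wxyz"),
                )
            )
            explained[f"{a}:{b}"] = i < n // 2
        return recs, pd.Series(explained)

    def test_informative_feature_ranks_first(self, rng):
        recs, explained = self._dimers(rng)
        proteins = [p for r in recs for p in (r.protein_a, r.protein_b)]
        informative = {
            p: float(explained[r.pair_id]) + rng.normal(0, 0.4)
            for r in recs
            for p in (r.protein_a, r.protein_b)
        }
        features = pd.DataFrame(
            {
                "informative": pd.Series(informative),
                "noise1": pd.Series({p: rng.normal() for p in proteins}),
                "noise2": pd.Series({p: rng.normal() for p in proteins}),
            }
        )
        out = explainability_logistic(explained, features, recs)
        assert out["q"].idxmin() == "informative"

    def test_constant_feature_flagged(self, rng):
        recs, explained = self._dimers(rng, n=20)
        proteins = [p for r in recs for p in (r.protein_a, r.protein_b)]
        features = pd.DataFrame(
            {
                "const": pd.Series({p: 1.0 for p in proteins}),
                "ok": pd.Series({p: rng.normal() for p in proteins}),
            }
        )
        out = explainability_logistic(explained, features, recs)
        assert np.isnan(out.loc["const", "coef"])

    def test_perfect_separation_handled(self, rng):
        recs, explained = self._dimers(rng, n=30)
        proteins = {p: float(explained[r.pair_id]) for r in recs for p in (r.protein_a, r.protein_b)}
        features = pd.DataFrame({"copy": pd.Series(proteins)})
        out = explainability_logistic(explained, features, recs)  # must not crash
        assert "copy" in out.index
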