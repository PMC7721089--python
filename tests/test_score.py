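import numpy as np
import pandas as pd
import pytest

from m6ametab.io import ClinicalTable, ExpressionMatrix
from m6ametab.score import (
    CoxScreenTable,
    SignaturePartition,
    compute_m6ascore,
    cox_screen,
    minmax_scale,
    score_groups,
    signature_partition,
)


def _survival_frame(times, events, ids=None):
    ids = ids or [f"S{i}" for i in range(len(times))]
    return ClinicalTable(
        pd.DataFrame(
            {"os_time": times, "os_event": events},
            index=pd.Index(ids, name="sample_id"),
        )
    )


def _simulate_survival_gene(beta, n, seed, baseline=0.1):
    """Exponential survival with log-hazard beta * x, uniform censoring."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 1.0, n)
    t = rng.exponential(1.0 / (baseline * np.exp(beta * x)))
    c = rng.uniform(0, 30, n)
    return x, np.minimum(t, c), (t <= c).astype(int)


class TestCoxScreen:
    def test_null_gene_rarely_significant(self):
        covered = 0
        for seed in range(20):
            x, t, e = _simulate_survival_gene(0.0, 500, seed)
            expr = ExpressionMatrix(
                pd.DataFrame([x], index=["G1"],
                             columns=[f"S{i}" for i in range(500)])
            )
            screen = cox_screen(expr, _survival_frame(t, e))
            row = screen.table.loc["G1"]
            covered += abs(row["log_hr"]) < 2 * row["se"]
        assert covered >= 18  # ~95% coverage

    def test_recovers_true_log_hazard(self):
        estimates = []
        for seed in range(50):
            x, t, e = _simulate_survival_gene(0.5, 1000, 1000 + seed)
            expr = ExpressionMatrix(
                pd.DataFrame([x], index=["G1"],
                             columns=[f"S{i}" for i in range(1000)])
            )
            screen = cox_screen(expr, _survival_frame(t, e))
            estimates.append(screen.table.loc["G1", "log_hr"])
        assert abs(np.mean(estimates) - 0.5) < 0.05

    def test_zero_variance_gene_excluded(self):
        x, t, e = _simulate_survival_gene(0.0, 60, 0)
        expr = ExpressionMatrix(
            pd.DataFrame([x, np.full(60, 3.0)], index=["G1", "G2"],
                         columns=[f"S{i}" for i in range(60)])
        )
        screen = cox_screen(expr, _survival_frame(t, e))
        assert "G2" in screen.excluded
        assert list(screen.table.index) == ["G1"]

    def test_too_few_events_errors(self):
        expr = ExpressionMatrix(
            pd.DataFrame(np.random.default_rng(0).normal(size=(2, 20)),
                         index=["G1", "G2"],
                         columns=[f"S{i}" for i in range(20)])
        )
        clin = _survival_frame([1.0] * 20, [0] * 20)
        with pytest.raises(ValueError, match="events"):
            cox_screen(expr, clin)


class TestSignaturePartition:
    def _screen(self, rows):
        table = pd.DataFrame(rows).set_index("gene")
        table["log_hr"] = np.log(table["hr"])
        return CoxScreenTable(table=table)

    def test_partition_rule(self):
        screen = self._screen([
            {"gene": "A", "hr": 2.0, "se": 0.1, "p": 0.01, "n_used": 100},
            {"gene": "B", "hr": 0.5, "se": 0.1, "p": 0.01, "n_used": 100},
            {"gene": "C", "hr": 1.5, "se": 0.5, "p": 0.50, "n_used": 100},
        ])
        part = signature_partition(screen)
        assert part.risk_genes == ["A"]
        assert part.protective_genes == ["B"]

    def test_all_non_significant_errors(self):
        screen = self._screen(
            [{"gene": "A", "hr": 1.2, "se": 1.0, "p": 0.9, "n_used": 10}]
        )
        with pytest.raises(ValueError, match="no gene passed"):
            signature_partition(screen)

    def test_hr_exactly_one_excluded_with_warning(self):
        screen = self._screen([
            {"gene": "A", "hr": 1.0, "se": 0.1, "p": 0.01, "n_used": 100},
            {"gene": "B", "hr": 2.0, "se": 0.1, "p": 0.01, "n_used": 100},
        ])
        with pytest.warns(UserWarning, match="HR exactly 1"):
            part = signature_partition(screen)
        assert part.genes == ["B"]

    def test_recovers_planted_prognostic_genes(self, default_cohort):
        cohort = default_cohort
        planted = cohort.truth_genes[
            cohort.truth_genes["role"].isin(
                ["risk_signature", "protective_signature"]
            )
        ]
        expr = cohort.expression.subset_genes(planted.index)
        screen = cox_screen(expr, cohort.clinical)
        part = signature_partition(screen)
        risk_true = set(
            planted.index[planted["role"] == "risk_signature"]
        )
        prot_true = set(
            planted.index[planted["role"] == "protective_signature"]
        )
        sens_risk = len(risk_true & set(part.risk_genes)) / len(risk_true)
        sens_prot = len(prot_true & set(part.protective_genes)) / len(prot_true)
        assert sens_risk >= 0.8
        assert sens_prot >= 0.8
        # no cross-contamination: planted risk genes never come out protective
        assert not risk_true & set(part.protective_genes)


class TestMinmaxScale:
    def test_affine_map_endpoints(self):
        df = pd.DataFrame({"a": [0.0], "b": [5.0], "c": [10.0]}, index=["G"])
        scaled, bounds = minmax_scale(df)
        assert list(scaled.loc["G"]) == [-1.0, 0.0, 1.0]
        assert bounds.loc["G", "min"] == 0.0 and bounds.loc["G", "max"] == 10.0

    def test_constant_gene_maps_to_zero(self):
        df = pd.DataFrame({"a": [3.0], "b": [3.0], "c": [3.0]}, index=["G"])
        with pytest.warns(UserWarning, match="constant"):
            scaled, _ = minmax_scale(df)
        assert (scaled.loc["G"] == 0.0).all()

    def test_rescaling_with_recorded_bounds_is_identity(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(4, 6)),
                          index=list("ABCD"), columns=list("uvwxyz"))
        scaled, bounds = minmax_scale(df)
        # scale the raw data again against the frozen bounds
        again, _ = minmax_scale(df, bounds=bounds)
        pd.testing.assert_frame_equal(scaled, again)


class TestComputeM6ascore:
    def _expr(self, data, samples=None):
        samples = samples or [f"S{i}" for i in range(len(next(iter(data.values()))))]
        return ExpressionMatrix(pd.DataFrame(data, index=samples).T)

    def test_symmetric_risk_protective_cancel(self):
        expr = self._expr({"R1": [0.0, 1.0, 2.0], "P1": [0.0, 1.0, 2.0]})
        part = SignaturePartition(["R1"], ["P1"], alpha=0.05)
        table = compute_m6ascore(expr, part)
        assert np.allclose(table.scores, 0.0)

    def test_all_minimum_closed_form(self):
        # R risk and P protective genes all at per-gene minimum: score = P - R
        expr = self._expr(
            {
                "R1": [0.0, 5.0, 9.0], "R2": [1.0, 2.0, 3.0],
                "P1": [0.0, 1.0, 2.0], "P2": [4.0, 5.0, 9.0],
                "P3": [2.0, 4.0, 8.0],
            }
        )
        part = SignaturePartition(["R1", "R2"], ["P1", "P2", "P3"], alpha=0.05)
        table = compute_m6ascore(expr, part)
        # sample S0 holds every gene's minimum -> all scaled to -1
        assert table.scores["S0"] == pytest.approx(3 - 2)

    def test_matches_spreadsheet_oracle_on_toy_matrix(self):
        # 4 genes x 3 samples, recomputed by hand with the affine map
        raw = {
            "R1": [2.0, 4.0, 6.0],
            "R2": [1.0, 1.5, 2.0],
            "P1": [0.0, 3.0, 6.0],
            "P2": [10.0, 10.5, 12.0],
        }
        expr = self._expr(raw)
        part = SignaturePartition(["R1", "R2"], ["P1", "P2"], alpha=0.05)
        table = compute_m6ascore(expr, part)

        def scale(vals):
            lo, hi = min(vals), max(vals)
            return [2 * (v - lo) / (hi - lo) - 1 for v in vals]

        scaled = {g: scale(v) for g, v in raw.items()}
        for j, s in enumerate(["S0", "S1", "S2"]):
            expected = (
                scaled["R1"][j] + scaled["R2"][j]
                - scaled["P1"][j] - scaled["P2"][j]
            )
            assert table.scores[s] == pytest.approx(expected)

    def test_monotone_in_risk_and_protective_genes(self):
        expr = self._expr(
            {"R1": [0.0, 5.0, 10.0], "P1": [0.0, 5.0, 10.0]}
        )
        part = SignaturePartition(["R1"], ["P1"], alpha=0.05)
        base = compute_m6ascore(expr, part).scores
        bumped = expr.data.copy()
        bumped.loc["R1", "S1"] += 2.0  # within recorded bounds [0, 10]
        up = compute_m6ascore(ExpressionMatrix(bumped), part).scores
        assert up["S1"] > base["S1"]
        bumped2 = expr.data.copy()
        bumped2.loc["P1", "S1"] += 2.0
        down = compute_m6ascore(ExpressionMatrix(bumped2), part).scores
        assert down["S1"] < base["S1"]

    def test_score_invariant_to_non_signature_genes(self):
        expr = self._expr(
            {"R1": [0.0, 5.0, 10.0], "P1": [1.0, 2.0, 3.0],
             "X1": [9.0, 9.0, 1.0]}
        )
        part = SignaturePartition(["R1"], ["P1"], alpha=0.05)
        base = compute_m6ascore(expr, part).scores
        altered = expr.data.copy()
        altered.loc["X1"] = [0.0, 100.0, -3.0]
        again = compute_m6ascore(ExpressionMatrix(altered), part).scores
        pd.testing.assert_series_equal(base, again)

    def test_no_signature_gene_present_errors(self, toy_expression):
        part = SignaturePartition(["NOPE"], [], alpha=0.05)
        with pytest.raises(ValueError, match="no signature gene"):
            compute_m6ascore(toy_expression, part)

    def test_signature_tsv_round_trip_scores_identically(self, tmp_path):
        expr = self._expr(
            {"R1": [2.0, 4.0, 6.0], "P1": [0.0, 3.0, 6.0]}
        )
        part = SignaturePartition(["R1"], ["P1"], alpha=0.05)
        base = compute_m6ascore(expr, part)  # freezes bounds on part
        path = tmp_path / "signature.tsv"
        part.to_tsv(path)
        reloaded = SignaturePartition.from_tsv(path)
        again = compute_m6ascore(expr, reloaded)
        pd.testing.assert_series_equal(base.scores, again.scores)


class TestScoreGroups:
    def _table(self, values):
        from m6ametab.score import ScoreTable

        return ScoreTable(
            scores=pd.Series(values,
                             index=[f"S{i}" for i in range(len(values))])
        )

    def test_median_split(self):
        table = score_groups(self._table([1.0, 2.0, 3.0, 4.0]))
        assert list(table.groups) == ["low", "low", "high", "high"]

    def test_tied_scores_all_low_with_warning(self):
        with pytest.warns(UserWarning, match="low score group"):
            table = score_groups(self._table([2.0, 2.0, 2.0]))
        assert (table.groups == "low").all()

    def test_balanced_split_for_distinct_scores(self):
        rng = np.random.default_rng(1)
        for n in (10, 11, 50, 51):
            table = score_groups(self._table(list(rng.normal(size=n))))
            counts = table.groups.value_counts()
            assert abs(counts.get("high", 0) - counts.get("low", 0)) <= 1

    def test_numeric_cutoff(self):
        table = score_groups(self._table([0.0, 1.0, 5.0]), cutoff=0.5)
        assert list(table.groups) == ["low", "high", "high"]
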