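import numpy as np
import pandas as pd
import pytest

from methsponge import survival as surv
from methsponge.synthetic_data import SimulationConfig, sample_ids, simulate_survival
from methsponge.types import ClinicalTable, MethylationProfile, ValidationError


def _binary_covariate_profile(n: int, seed: int = 0) -> MethylationProfile:
    """Balanced two-level methylation covariate (maximal spread on [0,1])."""
    samples = [f"T{i:03d}" for i in range(1, n + 1)]
    x = np.zeros(n)
    x[n // 2:] = 1.0
    values = pd.DataFrame([x], index=["gene1"], columns=samples)
    return MethylationProfile(values, "gene").validate()


def _exponential_clinical(profile, beta, rng, censor=0.0):
    x = profile.values.iloc[0].to_numpy()
    rate = 1e-3 * np.exp(beta * (x - x.mean()))
    t = rng.exponential(1.0 / rate)
    event = np.ones(len(t), dtype=int)
    table = pd.DataFrame({"time": t, "event": event}, index=profile.values.columns)
    return ClinicalTable(table).validate()


class TestFitCox:
    def test_recovers_planted_beta(self):
        rng = np.random.default_rng(10)
        profile = _binary_covariate_profile(500)
        clin = _exponential_clinical(profile, beta=1.0, rng=rng)
        model = surv.fit_cox(profile, clin)
        assert model.converged
        assert model.beta["gene1"] == pytest.approx(1.0, abs=0.2)

    def test_duplicated_covariate_is_collinearity_error(self):
        profile = _binary_covariate_profile(60)
        dup = pd.concat([profile.values, profile.values.rename(index={"gene1": "gene2"})])
        dup_profile = MethylationProfile(dup, "gene").validate()
        rng = np.random.default_rng(1)
        clin = _exponential_clinical(profile, beta=0.5, rng=rng)
        with pytest.raises(ValidationError, match="collinear"):
            surv.fit_cox(dup_profile, clin)

    def test_too_few_events_rejected(self):
        profile = _binary_covariate_profile(4)
        rng = np.random.default_rng(2)
        clin = _exponential_clinical(profile, beta=0.0, rng=rng)
        clin.table["event"] = [1, 0, 0, 0]
        with pytest.raises(ValidationError, match="events"):
            surv.fit_cox(profile, clin)


class TestPrognosticIndex:
    def _model(self, beta: dict) -> surv.CoxModel:
        return surv.CoxModel(
            covariates=list(beta), beta=pd.Series(beta),
            log_likelihood=0.0, converged=True,
        )

    @pytest.mark.parametrize(
        "beta,x,expected",
        [
            ({"g1": 2.0}, [0.5], 1.0),
            ({"g1": 1.0, "g2": -1.0}, [0.5, 0.5], 0.0),
            ({"g1": 0.5, "g2": 1.5}, [0.2, 0.4], 0.7),
        ],
    )
    def test_linear_combination(self, beta, x, expected):
        values = pd.DataFrame(
            {"S1": x, "S2": [v + 0.1 for v in x]}, index=list(beta)
        )
        profile = MethylationProfile(values, "gene").validate()
        assign = surv.prognostic_index(self._model(beta), profile)
        by_sample = {a.sample_id: a.pi for a in assign}
        assert by_sample["S1"] == pytest.approx(expected)

    def test_median_split_ties_to_low(self):
        values = pd.DataFrame(
            {"S1": [0.1], "S2": [0.2], "S3": [0.2], "S4": [0.3]}, index=["g1"]
        )
        profile = MethylationProfile(values, "gene").validate()
        assign = surv.prognostic_index(self._model({"g1": 1.0}), profile)
        groups = {a.sample_id: a.group for a in assign}
        # median PI = 0.2; ties assigned to the low-risk group
        assert groups == {"S1": "low", "S2": "low", "S3": "low", "S4": "high"}

    def test_affine_shift_leaves_split_unchanged(self):
        rng = np.random.default_rng(3)
        values = pd.DataFrame(
            rng.uniform(0.1, 0.6, size=(2, 20)),
            index=["g1", "g2"],
            columns=[f"S{i}" for i in range(20)],
        )
        model = self._model({"g1": 1.2, "g2": -0.4})
        a1 = surv.prognostic_index(model, MethylationProfile(values, "gene").validate())
        a2 = surv.prognostic_index(
            model, MethylationProfile(values + 0.3, "gene").validate()
        )
        assert [a.group for a in a1] == [a.group for a in a2]
        shift = 0.3 * (1.2 - 0.4)
        for u, v in zip(a1, a2):
            assert v.pi - u.pi == pytest.approx(shift)


class TestStratifyAndTest:
    def _clinical(self, times, events, samples):
        return ClinicalTable(
            pd.DataFrame({"time": times, "event": events}, index=samples)
        ).validate()

    def test_identical_groups_give_p_near_one(self):
        samples = [f"S{i}" for i in range(20)]
        times = list(range(1, 11)) * 2
        clin = self._clinical(times, [1] * 20, samples)
        assign = [
            surv.RiskAssignment(s, 0.0, "high" if i < 10 else "low")
            for i, s in enumerate(samples)
        ]
        res = surv.stratify_and_test(assign, clin)
        assert res["statistic"] == pytest.approx(0.0, abs=1e-9)
        assert res["p_value"] == pytest.approx(1.0, abs=1e-6)

    def test_km_starts_at_one_and_is_monotone(self):
        rng = np.random.default_rng(4)
        samples = [f"S{i}" for i in range(30)]
        clin = self._clinical(rng.exponential(100, 30), [1] * 30, samples)
        assign = [
            surv.RiskAssignment(s, float(i), "high" if i % 2 else "low")
            for i, s in enumerate(samples)
        ]
        res = surv.stratify_and_test(assign, clin)
        for g in ("high", "low"):
            km = res["km"][g]
            assert km["survival"].iloc[0] == pytest.approx(1.0)
            assert (km["survival"].diff().dropna() <= 1e-12).all()

    def test_separated_hazards_detected(self):
        rng = np.random.default_rng(5)
        n = 150
        samples = [f"S{i}" for i in range(2 * n)]
        t_high = rng.exponential(100 / 3, n)  # hazard ratio 3
        t_low = rng.exponential(100, n)
        clin = self._clinical(
            np.concatenate([t_high, t_low]), [1] * (2 * n), samples
        )
        assign = [
            surv.RiskAssignment(s, 0.0, "high" if i < n else "low")
            for i, s in enumerate(samples)
        ]
        assert surv.stratify_and_test(assign, clin)["p_value"] < 0.05

    def test_empty_group_is_error(self):
        clin = self._clinical([1, 2], [1, 1], ["S0", "S1"])
        assign = [surv.RiskAssignment(s, 0.0, "high") for s in ["S0", "S1"]]
        with pytest.raises(ValidationError, match="non-empty"):
            surv.stratify_and_test(assign, clin)


class TestSimulateSurvival:
    def test_monotone_hazard_gives_negative_kendall(self):
        cfg = SimulationConfig(rng_seed=2, n_tumor=200, censor_rate=0.0,
                               survival_beta=(3.0,))
        tumor, _, _ = sample_ids(cfg)
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            [rng.uniform(0, 1, len(tumor))], index=["g1"], columns=tumor
        )
        profile = MethylationProfile(values, "gene").validate()
        clin, risk = simulate_survival(cfg, profile)
        from scipy.stats import kendalltau

        tau = kendalltau(values.loc["g1", clin.table.index],
                         clin.table["time"]).statistic
        assert tau < 0
        assert (clin.table["event"] == 1).all()

    def test_full_censoring_boundary(self):
        cfg = SimulationConfig(rng_seed=3, censor_rate=1.0)
        tumor, _, _ = sample_ids(cfg)
        values = pd.DataFrame([np.linspace(0.2, 0.8, len(tumor))],
                              index=["g1"], columns=tumor)
        clin, _ = simulate_survival(
            cfg, MethylationProfile(values, "gene").validate()
        )
        assert (clin.table["event"] == 0).all()

    def test_censor_rate_is_respected(self):
        cfg = SimulationConfig(rng_seed=4, n_tumor=800, censor_rate=0.3,
                               survival_beta=(1.0,))
        tumor, _, _ = sample_ids(cfg)
        rng = np.random.default_rng(1)
        values = pd.DataFrame([rng.uniform(0, 1, len(tumor))],
                              index=["g1"], columns=tumor)
        clin, _ = simulate_survival(
            cfg, MethylationProfile(values, "gene").validate()
        )
        frac_censored = (clin.table["event"] == 0).mean()
        assert frac_censored == pytest.approx(0.3, abs=0.05)
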