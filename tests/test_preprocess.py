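import math

import numpy as np
import pytest
from scipy import stats as sps

from phosphoflow import preprocess, synthdata
from phosphoflow.preprocess import (
    PROV_COL_MEAN,
    PROV_KNN,
    PROV_MEASURED,
    PROV_ROW_MIN,
    ImputationError,
    NormalisationError,
    collapse_to_sites,
    compute_spikein_factors,
    filter_evidence,
    impute,
    presence_threshold,
    reproducible_sites,
)

from .conftest import make_matrix, make_record


class TestFilterEvidence:
    def test_threshold_inclusive(self):
        rec = make_record(localization_prob=0.75)
        assert filter_evidence([rec]) == [rec]

    def test_just_below_threshold_removed(self):
        assert filter_evidence([make_record(localization_prob=0.7499)]) == []

    def test_fixture_counts(self):
        rows = (
            [make_record(sample_id=f"k{i}") for i in range(14)]
            + [make_record(localization_prob=0.5) for _ in range(4)]
            + [make_record(is_contaminant=True) for _ in range(2)]
        )
        assert len(filter_evidence(rows)) == 14

    def test_reverse_removed(self):
        assert filter_evidence([make_record(is_reverse=True)]) == []


def spike_records(intensities: dict[str, dict[str, float]]):
    """sample -> standard -> intensity."""
    out = []
    for sample, stds in intensities.items():
        for std, val in stds.items():
            out.append(
                make_record(sample_id=sample, protein_id=std, gene_symbol=std,
                            position=1, localization_prob=1.0,
                            raw_intensity=val, is_spikein=True)
            )
    return out


class TestSpikeinFactors:
    AMOUNTS = {"A": 5.0, "B": 0.5, "C": 10.0}

    def test_identical_spikeins_give_unit_factors(self):
        recs = spike_records({
            "s1": {"A": 100.0, "B": 10.0, "C": 200.0},
            "s2": {"A": 100.0, "B": 10.0, "C": 200.0},
        })
        nf = compute_spikein_factors(recs, self.AMOUNTS)
        for f in nf.factors.values():
            assert f == pytest.approx(1.0, abs=1e-12)

    def test_uniform_2x_sample_hand_computed(self):
        # s2 spike-ins are uniformly 2x s1; reference per standard is the
        # geometric mean, so factors are (1/sqrt(2), sqrt(2)) and dividing
        # by them equalises the standards across samples.
        recs = spike_records({
            "s1": {"A": 100.0, "B": 10.0, "C": 200.0},
            "s2": {"A": 200.0, "B": 20.0, "C": 400.0},
        })
        nf = compute_spikein_factors(recs, self.AMOUNTS)
        assert nf.factors["s1"] == pytest.approx(1 / math.sqrt(2), rel=1e-12)
        assert nf.factors["s2"] == pytest.approx(math.sqrt(2), rel=1e-12)
        for std in self.AMOUNTS:
            normed = {
                s: nf.standard_intensities.loc[std, s] / nf.factors[s]
                for s in ("s1", "s2")
            }
            assert normed["s1"] == pytest.approx(normed["s2"], rel=1e-12)

    def test_robust_to_one_aberrant_standard(self):
        recs = spike_records({
            "s1": {"A": 100.0, "B": 10.0, "C": 200.0},
            "s2": {"A": 100.0, "B": 10.0, "C": 200.0 * 8},
        })
        nf = compute_spikein_factors(recs, self.AMOUNTS)
        # geometric mean over 3 standards: 8^(1/3)/ref adjustment, factor ratio 2
        assert nf.factors["s2"] / nf.factors["s1"] == pytest.approx(2.0, rel=1e-9)

    def test_sample_without_spikeins_fails_with_name(self):
        recs = spike_records({"s1": {"A": 100.0}}) + [make_record(sample_id="s2")]
        with pytest.raises(NormalisationError, match="s2"):
            compute_spikein_factors(recs, {"A": 5.0})

    def test_zero_intensity_spikein_fails(self):
        recs = spike_records({"s1": {"A": 0.0}})
        with pytest.raises(NormalisationError):
            compute_spikein_factors(recs, {"A": 5.0})

    def test_recovery_of_planted_scale_factors(self):
        cfg = synthdata.PhosphoSimConfig(seed=21, n_sites=150)
        records, amounts, truth = synthdata.simulate_phospho(cfg)
        nf = compute_spikein_factors(filter_evidence(records), amounts)
        planted = [truth.sample_scale_factors[s] for s in sorted(nf.factors)]
        recovered = [nf.factors[s] for s in sorted(nf.factors)]
        rho = sps.spearmanr(planted, recovered).statistic
        assert rho >= 0.95

    def test_idempotence(self):
        recs = spike_records({
            "s1": {"A": 130.0, "B": 11.0, "C": 190.0},
            "s2": {"A": 260.0, "B": 33.0, "C": 210.0},
        })
        nf = compute_spikein_factors(recs, self.AMOUNTS)
        renormed = [
            make_record(sample_id=r.sample_id, protein_id=r.protein_id, position=1,
                        localization_prob=1.0, is_spikein=True,
                        raw_intensity=r.raw_intensity / nf.factors[r.sample_id])
            for r in recs
        ]
        nf2 = compute_spikein_factors(renormed, self.AMOUNTS)
        for f in nf2.factors.values():
            assert f == pytest.approx(1.0, abs=1e-9)


def unit_factors(samples):
    import pandas as pd

    return preprocess.NormalisationFactors(
        factors={s: 1.0 for s in samples},
        standard_intensities=pd.DataFrame(index=[], columns=list(samples)),
        expected_amounts={},
    )


class TestCollapseToSites:
    CLASSES = {"s1": "a", "s2": "a", "s3": "b"}

    def test_single_row_log10(self):
        m = collapse_to_sites(
            [make_record(sample_id="s1", raw_intensity=1000.0)],
            unit_factors(["s1", "s2", "s3"]), self.CLASSES,
        )
        assert m.values.iloc[0]["s1"] == pytest.approx(3.0, abs=1e-12)

    def test_sum_then_log(self):
        rows = [make_record(sample_id="s1", raw_intensity=400.0),
                make_record(sample_id="s1", raw_intensity=600.0)]
        m = collapse_to_sites(rows, unit_factors(["s1", "s2", "s3"]), self.CLASSES)
        assert m.values.iloc[0]["s1"] == pytest.approx(3.0, abs=1e-12)

    def test_max_aggregate(self):
        rows = [make_record(sample_id="s1", raw_intensity=400.0),
                make_record(sample_id="s1", raw_intensity=600.0)]
        m = collapse_to_sites(rows, unit_factors(["s1", "s2", "s3"]), self.CLASSES,
                              aggregate="max")
        assert m.values.iloc[0]["s1"] == pytest.approx(np.log10(600.0), abs=1e-12)

    def test_missing_cell_count(self):
        rows = []
        for i in range(5):
            for s in ("s1", "s2", "s3"):
                if (i, s) in {(0, "s3"), (4, "s1")}:
                    continue
                rows.append(make_record(sample_id=s, protein_id=f"P{i}",
                                        raw_intensity=100.0))
        m = collapse_to_sites(rows, unit_factors(["s1", "s2", "s3"]), self.CLASSES)
        assert int(m.values.isna().sum().sum()) == 2
        assert int((~m.observed).sum().sum()) == 2

    def test_spikeins_excluded(self):
        rows = [make_record(sample_id="s1", raw_intensity=100.0),
                make_record(sample_id="s1", protein_id="STD", is_spikein=True,
                            raw_intensity=500.0, position=1, localization_prob=1.0)]
        m = collapse_to_sites(rows, unit_factors(["s1", "s2", "s3"]), self.CLASSES)
        assert len(m.sites) == 1


class TestPresenceThreshold:
    @pytest.mark.parametrize("n,frac,expected", [
        (8, 0.75, 6),   # six of eight
        (5, 0.75, 4),   # four of five
        (1, 0.75, 1),
        (21, 0.75, 16),
        (4, 0.5, 2),
        (10, 1.0, 10),
    ])
    def test_values(self, n, frac, expected):
        assert presence_threshold(n, frac) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            presence_threshold(0, 0.75)
        with pytest.raises(ValueError):
            presence_threshold(5, 0.0)
        with pytest.raises(ValueError):
            presence_threshold(5, 1.2)


class TestReproducibleSites:
    def labels(self):
        cls = {}
        for c, n in [("p53", 8), ("PyMT", 8), ("Her2", 5)]:
            for i in range(n):
                cls[f"{c}{i}"] = c
        return cls

    def build(self, counts_per_class):
        """One site observed in the given number of samples of each class."""
        cls = self.labels()
        samples = list(cls)
        obs = np.zeros((1, len(samples)), dtype=bool)
        taken = {c: 0 for c in ("p53", "PyMT", "Her2")}
        for j, s in enumerate(samples):
            c = cls[s]
            if taken[c] < counts_per_class[c]:
                obs[0, j] = True
                taken[c] += 1
        vals = np.where(obs, 4.0, np.nan)
        return make_matrix(vals, cls, observed=obs)

    def test_six_of_eight_retained(self):
        m = self.build({"p53": 6, "PyMT": 0, "Her2": 0})
        assert reproducible_sites(m) == set(m.sites)

    def test_below_all_thresholds_excluded(self):
        m = self.build({"p53": 5, "PyMT": 5, "Her2": 3})
        assert reproducible_sites(m) == set()

    def test_brute_force_oracle(self, rng):
        cls = self.labels()
        n_sites = 60
        obs = rng.random((n_sites, len(cls))) < 0.6
        vals = np.where(obs, 4.0, np.nan)
        m = make_matrix(vals, cls, observed=obs)
        got = reproducible_sites(m, fraction=0.75)
        # independent brute force over sites and classes
        expected = set()
        samples = list(cls)
        for i, site in enumerate(m.sites):
            for c in ("p53", "PyMT", "Her2"):
                cols = [j for j, s in enumerate(samples) if cls[s] == c]
                n_obs = sum(obs[i, j] for j in cols)
                if n_obs >= math.ceil(0.75 * len(cols) - 1e-12):
                    expected.add(site)
        assert got == expected

    def test_fraction_monotonicity(self, rng):
        cls = self.labels()
        obs = rng.random((40, len(cls))) < 0.6
        m = make_matrix(np.where(obs, 4.0, np.nan), cls, observed=obs)
        prev = None
        for frac in (0.25, 0.5, 0.75, 1.0):
            cur = reproducible_sites(m, fraction=frac)
            if prev is not None:
                assert cur <= prev
            prev = cur


class TestImpute:
    def test_no_missing_identity(self, rng):
        cls = {"a1": "a", "a2": "a", "b1": "b", "b2": "b"}
        vals = rng.normal(4, 1, (6, 4))
        m = make_matrix(vals, cls)
        out = impute(m)
        assert np.allclose(out.values.to_numpy(), vals)
        assert (out.provenance == PROV_MEASURED).all().all()

    def test_routing_boundary_21_samples(self, rng):
        cls = {f"s{i}": ("a" if i < 11 else "b") for i in range(21)}
        vals = rng.normal(4, 0.5, (2, 21))
        obs = np.ones((2, 21), dtype=bool)
        obs[0, 11:] = False   # site 0: observed in 11/21 (> 50%) -> knn
        obs[1, 10:] = False   # site 1: observed in 10/21 (<= 50%) -> fallback
        vals = np.where(obs, vals, np.nan)
        m = make_matrix(vals, cls, observed=obs)
        out = impute(m, k=3, fallback="row_min")
        assert set(out.provenance.iloc[0, 11:]) == {PROV_KNN}
        assert set(out.provenance.iloc[1, 10:]) == {PROV_ROW_MIN}
        site1_min = np.nanmin(vals[1])
        assert np.allclose(out.values.iloc[1, 10:], site1_min)

    def test_col_mean_fallback(self):
        cls = {"s1": "a", "s2": "a", "s3": "b", "s4": "b"}
        vals = np.array([
            [1.0, 2.0, 3.0, 4.0],
            [np.nan, np.nan, np.nan, 8.0],  # 1/4 observed -> fallback
        ])
        m = make_matrix(vals, cls)
        out = impute(m, fallback="col_mean")
        # column means over observed cells
        assert out.values.iloc[1, 0] == pytest.approx(1.0)
        assert out.values.iloc[1, 1] == pytest.approx(2.0)
        assert set(out.provenance.iloc[1, :3]) == {PROV_COL_MEAN}

    def test_knn_exact_recovery_rank1_duplicates(self, rng):
        # groups of identical rows: each row's nearest neighbours are exact
        # duplicates, so k-NN reproduces held-out values exactly
        k = 4
        cls = {f"s{i}": ("a" if i < 5 else "b") for i in range(10)}
        base = rng.normal(4, 1, (6, 10))
        vals = np.repeat(base, k + 1, axis=0)  # 30 rows in groups of 5
        truth = vals.copy()
        obs = np.ones(vals.shape, dtype=bool)
        holes = rng.random(vals.shape) < 0.1
        # keep each row >50% observed, and within each duplicate group allow
        # at most one hole per column so all k neighbours observe the target
        for i in range(vals.shape[0]):
            if holes[i].sum() > 3:
                holes[i, :] = False
        for g in range(0, vals.shape[0], k + 1):
            block = holes[g : g + k + 1]
            for j in range(vals.shape[1]):
                hit = np.nonzero(block[:, j])[0]
                block[hit[1:], j] = False
        obs &= ~holes
        m = make_matrix(np.where(obs, vals, np.nan), cls, observed=obs)
        out = impute(m, k=k, fallback="row_min")
        assert np.allclose(out.values.to_numpy(), truth, atol=1e-6)

    def test_observed_cells_never_altered(self, rng):
        cls = {f"s{i}": ("a" if i < 4 else "b") for i in range(8)}
        vals = rng.normal(4, 1, (12, 8))
        obs = rng.random(vals.shape) < 0.8
        obs[:, 0] = True  # keep every site observed somewhere
        m = make_matrix(np.where(obs, vals, np.nan), cls, observed=obs)
        out = impute(m, k=3)
        assert np.allclose(out.values.to_numpy()[obs], vals[obs])
        assert (out.provenance.to_numpy()[obs] == PROV_MEASURED).all()

    def test_routing_provenance_consistent(self, rng):
        cls = {f"s{i}": ("a" if i < 4 else "b") for i in range(9)}
        vals = rng.normal(4, 1, (30, 9))
        obs = rng.random(vals.shape) < 0.6
        obs[:, 0] = True
        m = make_matrix(np.where(obs, vals, np.nan), cls, observed=obs)
        out = impute(m, k=3, fallback="row_min")
        n = 9
        for i in range(30):
            frac_gt_half = obs[i].sum() * 2 > n
            tags = set(out.provenance.iloc[i][~obs[i]])
            if not tags:
                continue
            assert tags == ({PROV_KNN} if frac_gt_half else {PROV_ROW_MIN})

    def test_zero_observation_site_errors(self):
        cls = {"s1": "a", "s2": "a", "s3": "b", "s4": "b"}
        vals = np.array([[1.0, 2.0, 3.0, 4.0], [np.nan] * 4])
        m = make_matrix(vals, cls)
        with pytest.raises(ImputationError):
            impute(m)

    def test_bad_fallback_name(self):
        cls = {"s1": "a", "s2": "a"}
        m = make_matrix(np.ones((2, 2)), cls)
        with pytest.raises(ValueError):
            impute(m, fallback="bogus")


class TestMatrixSerialisation:
    def test_round_trip(self, tmp_path, rng):
        cls = {"s1": "a", "s2": "a", "s3": "b", "s4": "b"}
        vals = rng.normal(4, 1, (5, 4))
        vals[0, 1] = np.nan
        m = make_matrix(vals, cls)
        m.write(tmp_path / "m.tsv", tmp_path / "m.json")
        back = preprocess.IntensityMatrix.read(tmp_path / "m.tsv", tmp_path / "m.json")
        assert np.allclose(back.values.to_numpy(), vals, equal_nan=True)
        assert back.class_of == cls
        assert back.observed.equals(m.observed)


class TestEndToEndPreprocess:
    def test_full_chain_on_synthetic(self):
        cfg = synthdata.PhosphoSimConfig(seed=5, n_sites=120)
        records, amounts, truth = synthdata.simulate_phospho(cfg)
        full, imputed, factors = preprocess.preprocess_evidence(
            records, amounts, truth.class_of
        )
        assert imputed.is_complete()
        assert set(imputed.samples) == set(truth.sample_ids)
        assert len(imputed.sites) <= len(full.sites)
        # normalisation must remove most of the planted scale variation:
        # normalised spike-in CV across samples far below raw CV
        import pandas as pd

        raw = pd.Series({s: truth.sample_scale_factors[s] for s in full.samples})
        est = pd.Series(factors.factors)
        resid = (np.log10(raw) - np.log10(est)).std()
        assert resid < np.log10(raw).std() * 0.5 or resid < 0.02
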