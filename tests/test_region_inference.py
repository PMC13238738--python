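"""NB tail test, BH adjustment, enrichment/z scores, presence calls, run_sample."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chromcall as cc
from chromcall.genome_io import GenomicInterval
from conftest import load_dataset


def nb_tail_by_pmf_summation(y: int, mu: float, theta: float) -> float:
    """Independent oracle: 1 - sum_{k<y} pmf(k) via the pmf recurrence.

    NB pmf:      f(0) = (theta/(theta+mu))^theta,
                 f(k+1) = f(k) * (k+theta)/(k+1) * mu/(mu+theta)
    Poisson pmf: f(0) = e^-mu, f(k+1) = f(k) * mu/(k+1)
    """
    if y == 0:
        return 1.0
    if mu == 0:
        return 0.0
    if math.isinf(theta):
        f = math.exp(-mu)
        acc = f
        for k in range(y - 1):
            f *= mu / (k + 1)
            acc += f
    else:
        f = (theta / (theta + mu)) ** theta
        acc = f
        for k in range(y - 1):
            f *= (k + theta) / (k + 1) * mu / (mu + theta)
            acc += f
    return 1.0 - acc


def bh_step_up_reference(p: np.ndarray) -> np.ndarray:
    """Independent BH oracle: p(i)*m/i, cumulative min from the largest."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestNbTailPvalue:
    def test_zero_count_covers_whole_support(self):
        assert cc.nb_tail_pvalue(0, 5.0, 2.0) == 1.0
        assert cc.nb_tail_pvalue(0, 5.0, cc.INFINITE) == 1.0

    def test_poisson_closed_form(self):
        # P(Y >= 1 | Poisson(1)) = 1 - e^-1
        assert cc.nb_tail_pvalue(1, 1.0, cc.INFINITE) == pytest.approx(
            1 - math.exp(-1), abs=1e-12
        )

    def test_geometric_closed_form(self):
        # theta=1 is geometric: P(Y >= 2 | mu=1) = (mu/(mu+1))^2 = 0.25
        assert cc.nb_tail_pvalue(2, 1.0, 1.0) == pytest.approx(0.25, abs=1e-12)

    def test_degenerate_zero_expectation(self):
        assert cc.nb_tail_pvalue(3, 0.0, 2.0) == 0.0
        assert cc.nb_tail_pvalue(0, 0.0, 2.0) == 1.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            cc.nb_tail_pvalue(-1, 1.0, 1.0)
        with pytest.raises(ValueError):
            cc.nb_tail_pvalue(1, 1.0, -2.0)

    def test_matches_pmf_summation_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            y = int(rng.integers(0, 51))
            mu = float(rng.uniform(0.01, 20.0))
            theta = float(rng.choice([0.5, 1.0, 5.0]))
            expect = nb_tail_by_pmf_summation(y, mu, theta)
            assert cc.nb_tail_pvalue(y, mu, theta) == pytest.approx(
                expect, abs=1e-12
            )

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        y=st.integers(0, 80),
        mu=st.floats(0.01, 30.0),
        theta=st.floats(0.2, 50.0),
    )
    def test_monotone_nonincreasing_in_y(self, y, mu, theta):
        assert cc.nb_tail_pvalue(y + 1, mu, theta) <= cc.nb_tail_pvalue(
            y, mu, theta
        )

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        y=st.integers(1, 80),
        mu=st.floats(0.5, 20.0),
        theta1=st.floats(0.2, 5.0),
        factor=st.floats(1.5, 20.0),
    )
    def test_heavier_overdispersion_is_more_conservative(
        self, y, mu, theta1, factor
    ):
        # Deep in the upper tail, smaller theta (heavier overdispersion)
        # gives the larger tail probability, i.e. a more conservative test.
        # (Just above the mean the ordering can invert, because heavy
        # overdispersion also concentrates mass at zero.)
        sd = math.sqrt(mu + mu * mu / theta1)
        if y <= mu + 3 * sd:
            return
        theta2 = theta1 * factor
        assert (
            cc.nb_tail_pvalue(y, mu, theta1)
            >= cc.nb_tail_pvalue(y, mu, theta2) - 1e-15
        )

    def test_poisson_limit_at_large_theta(self):
        ys = np.arange(0, 101)
        for mu in (0.5, 5.0, 20.0, 50.0):
            mus = np.full_like(ys, mu, dtype=float)
            diff = np.abs(
                cc.nb_tail_pvalues(ys, mus, 1e6)
                - cc.nb_tail_pvalues(ys, mus, cc.INFINITE)
            )
            assert diff.max() < 1e-4


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert cc.bh_adjust(np.array([0.03])).tolist() == [0.03]

    def test_hand_run_step_up(self):
        adj = cc.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert cc.bh_adjust(np.ones(5)).tolist() == [1.0] * 5

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cc.bh_adjust(np.array([0.5, 1.5]))

    def test_adjusted_at_least_raw_and_in_unit_interval(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=200)
        adj = cc.bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        assert ((adj >= 0) & (adj <= 1)).all()

    def test_matches_reference_on_random_vectors(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            n = int(rng.integers(1, 5000))
            p = rng.uniform(size=n) ** rng.uniform(0.5, 3.0)
            assert np.allclose(cc.bh_adjust(p), bh_step_up_reference(p),
                               atol=1e-12)


class TestScores:
    def test_enrichment_score_identity_and_examples(self):
        assert cc.enrichment_score(4, 4.0) == 0.0
        assert cc.enrichment_score(7, 1.0, epsilon=1.0) == pytest.approx(2.0)
        assert cc.enrichment_score(0, 0.0, epsilon=1.0) == 0.0

    def test_enrichment_score_requires_positive_epsilon(self):
        with pytest.raises(ValueError):
            cc.enrichment_score(1, 1.0, epsilon=0.0)

    def test_z_score_examples(self):
        assert cc.z_score(4, 4.0, 2.0) == 0.0
        assert cc.z_score(8, 4.0, cc.INFINITE) == pytest.approx(2.0)
        assert cc.z_score(8, 4.0, 4.0) == pytest.approx(4 / math.sqrt(8))

    def test_z_score_nan_for_zero_expectation(self):
        assert math.isnan(cc.z_score(3, 0.0, 2.0))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(y=st.integers(0, 100), mu=st.floats(0.1, 30), theta=st.floats(0.2, 50))
    def test_scores_monotone_in_y(self, y, mu, theta):
        assert cc.enrichment_score(y + 1, mu) > cc.enrichment_score(y, mu)
        assert cc.z_score(y + 1, mu, theta) > cc.z_score(y, mu, theta)
        assert np.sign(cc.z_score(y, mu, theta)) == np.sign(y - mu)


class TestCallPresence:
    def test_default_thresholds(self):
        assert cc.call_presence(2.0, 0.01) == 1
        assert cc.call_presence(1.0, 0.01) == 0
        assert cc.call_presence(2.0, 0.5) == 0

    def test_strict_inequalities(self):
        assert cc.call_presence(1.5, 0.01) == 0   # score must exceed
        assert cc.call_presence(2.0, 0.25) == 0   # padj must be below

    def test_blacklisted_is_na(self):
        assert cc.call_presence(2.0, 0.01, blacklisted=True) is pd.NA


class TestRunSample:
    def test_table_structure_and_blacklist_na(self, spikein_dataset):
        _, manifest = spikein_dataset
        sizes, regions, tiling, exp, ctrl = load_dataset(manifest)
        # blacklist the first region by hand
        flags = regions.blacklisted.copy()
        flags[0] = True
        regions = cc.RegionSet(regions=regions.regions, names=regions.names,
                               width=regions.width, blacklisted=flags)
        table = cc.run_sample(exp, ctrl, regions, tiling)
        assert list(table["name"]) == regions.names
        row0 = table.iloc[0]
        assert row0["call"] is pd.NA
        assert math.isnan(row0["p"]) and math.isnan(row0["padj"])
        ok = table.iloc[1:]
        assert (ok["padj"] >= ok["p"] - 1e-15).all()
        assert (ok["m"] >= 1.0).all()
        assert np.allclose(
            table["lambda_t"],
            table["m"] * table.attrs["background_model"].lambda_g,
        )

    def test_self_control_degeneracy(self, spikein_dataset):
        """With the experiment as its own control, sub-background regions
        are never called and scores are bounded by the no-control score."""
        _, manifest = spikein_dataset
        sizes, regions, tiling, exp, _ = load_dataset(manifest)
        table = cc.run_sample(exp, exp, regions, tiling)
        lam_g = table.attrs["background_model"].lambda_g
        sub = table[table["y"] <= lam_g]
        assert not (sub["call"] == 1).any()
        bound = cc.enrichment_score(
            table["y"].to_numpy(), np.full(len(table), lam_g)
        )
        assert (table["score"].to_numpy() <= bound + 1e-12).all()

    def test_mismatched_chromosomes_warn_zero_counts(self, caplog):
        track = cc.MidpointTrack.from_positions({"chrX": [1, 2, 3]})
        regions = cc.RegionSet(
            regions=[GenomicInterval("chr1", 0, 2000)], names=["a"], width=2000
        )
        tiling = cc.tile_genome({"chr1": 10000}, 2000, [])
        with caplog.at_level("WARNING"):
            table = cc.run_sample(track, None, regions, tiling)
        assert table["y"].tolist() == [0]
        assert any("share no chromosome" in r.message for r in caplog.records)

    def test_tsv_roundtrip(self, tmp_path, null_dataset):
        _, manifest = null_dataset
        sizes, regions, tiling, exp, _ = load_dataset(manifest)
        table = cc.run_sample(exp, None, regions, tiling)
        path = tmp_path / "calls.tsv"
        cc.write_calls_tsv(table, path)
        back = cc.read_calls_tsv(path)
        assert list(back.columns)[:4] == ["chrom", "start", "end", "name"]
        assert back["name"].tolist() == table["name"].tolist()
        assert back["y"].tolist() == table["y"].tolist()
        assert np.allclose(back["p"], table["p"], rtol=1e-4)
        assert (back["call"] == table["call"]).all()

    def test_increasing_control_count_never_helps(self):
        """Once the control ratio passes 1, more control signal can only
        shrink the score and grow the p-value."""
        model_lam, theta = 10.0, 5.0
        y = 30
        scores, pvals = [], []
        for y_ctrl in (10, 20, 40, 80):
            m = cc.compute_modulation(np.array([y_ctrl]), 10.0)[0]
            lam_t = m * model_lam
            scores.append(cc.enrichment_score(y, lam_t))
            pvals.append(cc.nb_tail_pvalue(y, lam_t, theta))
        assert all(a >= b for a, b in zip(scores, scores[1:]))
        assert all(a <= b for a, b in zip(pvals, pvals[1:]))
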