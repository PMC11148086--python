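import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from okseq import (
    ValidationError,
    fit_decay_curve,
    paired_bin_ttest,
    random_control_sites,
    reldist_histogram,
    relative_distances,
)
from okseq.reldist_stats import N_BINS, RelDistHistogram


def brute_force_reldist(a_points, b_points):
    """All-pairs nearest-flank search, independent of the searchsorted path."""
    out = []
    for chrom, a_list in a_points.items():
        b = sorted(b_points.get(chrom, ()))
        if len(b) < 2:
            continue
        for a in a_list:
            left = [x for x in b if x <= a]
            right = [x for x in b if x >= a]
            if a in b:
                out.append(0.0)
                continue
            if not left or not right:
                continue
            bl, br = max(left), min(right)
            out.append(min(a - bl, br - a) / (br - bl))
    return sorted(out)


class TestRelativeDistances:
    def test_hand_arithmetic(self):
        d, dropped = relative_distances({"c": [25]}, {"c": [0, 100]})
        assert d.tolist() == [0.25] and dropped == 0

    def test_midpoint_is_half(self):
        d, _ = relative_distances({"c": [50]}, {"c": [0, 100]})
        assert d.tolist() == [0.5]

    def test_coincident_point_is_zero(self):
        d, _ = relative_distances({"c": [0, 100]}, {"c": [0, 100]})
        assert d.tolist() == [0.0, 0.0]

    def test_points_outside_span_dropped_and_counted(self):
        d, dropped = relative_distances({"c": [-5, 25, 300]}, {"c": [0, 100]})
        assert d.tolist() == [0.25] and dropped == 2

    def test_chrom_with_one_reference_dropped(self):
        d, dropped = relative_distances({"c": [5, 10]}, {"c": [7]})
        assert d.size == 0 and dropped == 2

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_bruteforce(self, seed):
        r = np.random.default_rng(seed)
        a = {"c1": r.integers(0, 1000, 50).tolist(), "c2": r.integers(0, 500, 20).tolist()}
        b = {"c1": np.unique(r.integers(0, 1000, 8)).tolist(), "c2": [400]}
        d, dropped = relative_distances(a, b)
        assert sorted(d.tolist()) == pytest.approx(brute_force_reldist(a, b))
        assert len(d) + dropped == 70

    def test_matches_bedtools_reldist(self, tmp_path):
        """The canonical interval tool computes identical per-bin counts."""
        import shutil
        import subprocess

        if shutil.which("bedtools") is None:
            pytest.skip("bedtools not on PATH")
        r = np.random.default_rng(9)
        b = np.sort(r.choice(1_000_000, 20, replace=False))
        a = np.sort(r.choice(1_000_000, 300, replace=False))
        for name, pts in (("a.bed", a), ("b.bed", b)):
            (tmp_path / name).write_text("".join(f"chr1\t{x}\t{x + 1}\n" for x in pts))
        res = subprocess.run(
            ["bedtools", "reldist", "-a", str(tmp_path / "a.bed"), "-b", str(tmp_path / "b.bed")],
            capture_output=True, text=True, check=True,
        )
        ref = {}
        for line in res.stdout.splitlines()[1:]:
            reldist, count, total, _ = line.split("\t")
            ref[int(round(float(reldist) * 100))] = int(count)
        d, _ = relative_distances({"chr1": a}, {"chr1": b})
        h = reldist_histogram(d)
        ours = {i: int(round(p * h.n)) for i, p in enumerate(h.proportions) if p > 0}
        assert ours == ref
        assert h.n == int(res.stdout.splitlines()[1].split("\t")[2])

    def test_null_is_uniform_with_mean_quarter(self):
        r = np.random.default_rng(7)
        b = {"c": np.sort(r.choice(50_000_000, 100, replace=False))}
        a = {"c": r.choice(50_000_000, 10_000, replace=False)}
        d, _ = relative_distances(a, b)
        assert d.mean() == pytest.approx(0.25, abs=0.01)


class TestHistogram:
    def test_direct_binning(self):
        h = reldist_histogram([0.0, 0.004, 0.25])
        assert h.proportions[0] == pytest.approx(2 / 3)
        assert h.proportions[25] == pytest.approx(1 / 3)
        assert h.n == 3

    def test_empty_input(self):
        h = reldist_histogram([])
        assert h.n == 0 and h.proportions.sum() == 0.0

    def test_degenerate_all_zero(self):
        assert reldist_histogram([0.0] * 5).proportions[0] == 1.0

    def test_maximal_value_in_last_bin(self):
        assert reldist_histogram([0.5]).proportions[N_BINS - 1] == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            reldist_histogram([0.6])

    def test_proportions_sum_to_one_on_uniform_draws(self):
        d = np.random.default_rng(3).uniform(0, 0.5, 10_000)
        h = reldist_histogram(d)
        assert h.proportions.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.abs(h.proportions[:50] - 0.02) < 0.005)


def _hist(props):
    props = np.asarray(props, dtype=float)
    full = np.zeros(N_BINS)
    full[: len(props)] = props
    full[len(props)] = 1.0 - props.sum()  # park the remainder in one bin
    edges = np.round(np.arange(N_BINS + 1) * 0.01, 10)
    return RelDistHistogram(edges, full, 1000)


class TestPairedBinTTest:
    def test_closed_form_worked_example(self):
        res = paired_bin_ttest(_hist([0.10, 0.09, 0.08]), _hist([0.05, 0.05, 0.04]), 3, "greater")
        assert res.t_stat == pytest.approx(13.0, abs=1e-9)
        expected_p = 0.5 * (1 - 13.0 / np.sqrt(2 + 13.0**2))  # Student t tail, df=2
        assert res.p_value == pytest.approx(expected_p, abs=1e-4)
        assert res.p_value == pytest.approx(0.00293, abs=1e-4)

    def test_identical_histograms_convention(self):
        h = _hist([0.1, 0.1, 0.1])
        res = paired_bin_ttest(h, h, 3, "greater")
        assert (res.t_stat, res.p_value) == (0.0, 1.0)

    def test_swap_antisymmetry(self):
        ha, hb = _hist([0.2, 0.15, 0.1]), _hist([0.05, 0.08, 0.02])
        p1 = paired_bin_ttest(ha, hb, 3, "greater").p_value
        p2 = paired_bin_ttest(hb, ha, 3, "less").p_value
        assert p1 == pytest.approx(p2)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValidationError):
            paired_bin_ttest(_hist([0.1]), _hist([0.1]), 1, "greater")


class TestDecayCurve:
    def test_recovers_exact_parameters(self):
        edges = np.round(np.arange(N_BINS + 1) * 0.01, 10)
        x = edges[:-1] + 0.005
        y = 0.1 * np.exp(-x / 0.05) + 0.0196
        hist = RelDistHistogram(edges, y, n=0)  # n=0: exact curve, not a sample
        fit = fit_decay_curve(hist)
        assert fit.a == pytest.approx(0.1, abs=1e-6)
        assert fit.lam == pytest.approx(0.05, abs=1e-6)
        assert fit.c == pytest.approx(0.0196, abs=1e-6)
        lo, hi = fit.confidence_band(x)
        assert np.all(lo <= hi)

    def test_flat_histogram_gives_floor(self):
        edges = np.round(np.arange(N_BINS + 1) * 0.01, 10)
        flat = RelDistHistogram(edges, np.full(N_BINS, 1.0 / N_BINS), 1000)
        fit = fit_decay_curve(flat)
        assert abs(fit.a) < 1e-6
        assert fit.c == pytest.approx(1.0 / N_BINS, abs=1e-6)

    def test_noisy_uniform_sample_fits_nearly_constant(self):
        d = np.random.default_rng(5).uniform(0, 0.4999, 20_000)
        fit = fit_decay_curve(reldist_histogram(d))
        r = np.array([0.0, 0.25, 0.5])
        assert np.ptp(fit.predict(r)) < 0.01  # within half a uniform bin height

    def test_too_few_populated_bins_rejected(self):
        with pytest.raises(ValidationError):
            fit_decay_curve(reldist_histogram([0.0, 0.1, 0.2]))


class TestRandomControlSites:
    def test_cardinality_and_range(self):
        sites = random_control_sites({"c": 1_000_000}, {"c": 3}, seed=0)
        assert len(sites["c"]) == len(set(sites["c"].tolist())) == 3
        assert sites["c"].min() >= 0 and sites["c"].max() < 1_000_000

    def test_deterministic_given_seed(self):
        a = random_control_sites({"c": 10_000}, {"c": 50}, seed=9)
        b = random_control_sites({"c": 10_000}, {"c": 50}, seed=9)
        assert np.array_equal(a["c"], b["c"])

    def test_count_exceeding_positions_rejected(self):
        with pytest.raises(ValidationError):
            random_control_sites({"c": 10}, {"c": 11}, seed=0)

    def test_reldist_of_random_sites_is_uniform(self):
        r = np.random.default_rng(11)
        b = {"c": np.sort(r.choice(50_000_000, 120, replace=False))}
        sites = random_control_sites({"c": 50_000_000}, {"c": 5000}, seed=13)
        d, _ = relative_distances(sites, b)
        counts = reldist_histogram(d).proportions[:50] * len(d)
        p = stats.chisquare(counts, f_exp=np.full(50, counts.sum() / 50)).pvalue
        assert p > 0.01
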