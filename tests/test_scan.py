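"""Windowing, nuisance-parameter estimation, scan and locus scoring."""

import numpy as np
import pytest

from betascan2 import (
    BetaScanError,
    NeutralGenSpec,
    ScanConfig,
    SiteRecord,
    attach_percentiles,
    empirical_percentiles,
    estimate_divergence_scalar,
    estimate_theta,
    gen_neutral,
    iterate_windows,
    read_sites,
    scan,
    score_locus,
)


def sites_at(positions, count=5, n=10):
    return [SiteRecord(position=p, count=count, n=n) for p in positions]


class TestIterateWindows:
    def test_half_open_window_convention(self):
        """window=1000 around 5500 collects [5000, 6000), core excluded."""
        positions = [4999, 5000, 5500, 5999, 6000]
        sites = sites_at(positions)
        config = ScanConfig(statistic="B1", window=1000, min_core_freq=0.0)
        windows = {core.position: win for core, win in iterate_windows(sites, config)}
        assert windows[5500].S == 2  # 5000 and 5999 only

    def test_rare_cores_skipped(self):
        sites = [
            SiteRecord(100, 1, 50),   # folded freq 0.02
            SiteRecord(200, 25, 50),
        ]
        config = ScanConfig(statistic="B1", min_core_freq=0.05)
        cores = [core.position for core, _ in iterate_windows(sites, config)]
        assert cores == [200]

    def test_high_frequency_core_passes_folded_filter(self):
        sites = [SiteRecord(100, 48, 50), SiteRecord(200, 25, 50)]
        config = ScanConfig(statistic="B1", min_core_freq=0.05)
        cores = [c.position for c, _ in iterate_windows(sites, config)]
        assert cores == [200]  # folded freq of count 48 is 0.04

    def test_substitutions_are_never_cores_but_fill_D(self):
        sites = [SiteRecord(100, 5, 10), SiteRecord(150, 10, 10)]
        config = ScanConfig(statistic="B2", min_core_freq=0.0)
        [(core, win)] = list(iterate_windows(sites, config))
        assert core.position == 100 and win.D == 1 and win.S == 0

    def test_nearby_cores_share_window_contents(self):
        rng = np.random.default_rng(11)
        positions = np.sort(rng.choice(20000, size=300, replace=False)) + 1
        sites = sites_at(positions.tolist())
        config = ScanConfig(statistic="B1", window=1000, min_core_freq=0.0)
        wins = dict(
            (core.position, win) for core, win in iterate_windows(sites, config)
        )
        # brute-force oracle for each core
        for pos, win in wins.items():
            expected = [
                p for p in positions if pos - 500 <= p < pos + 500 and p != pos
            ]
            assert win.S == len(expected)


class TestParameterEstimation:
    def test_theta_from_polymorphic_sites(self):
        sites = sites_at(range(1, 12), count=2, n=4)  # 11 SNPs
        assert estimate_theta(sites, n=4, total_span=1000) == pytest.approx(0.006)

    def test_doubling_span_halves_theta(self):
        sites = sites_at(range(1, 12), count=2, n=4)
        a = estimate_theta(sites, n=4, total_span=1000)
        b = estimate_theta(sites, n=4, total_span=2000)
        assert b == pytest.approx(a / 2)

    def test_no_polymorphic_sites_is_an_error(self):
        subs = [SiteRecord(p, 4, 4) for p in (10, 20)]
        with pytest.raises(BetaScanError):
            estimate_theta(subs, n=4, total_span=100)

    def test_divergence_scalar_rearrangement(self):
        sites = sites_at(range(1, 1101), count=2, n=4)  # 1100 SNPs
        sites += [SiteRecord(p, 4, 4) for p in range(2000, 3200)]  # 1200 subs
        assert estimate_divergence_scalar(sites, n=4) == pytest.approx(2.0)

    def test_divergence_needs_both_site_classes(self):
        with pytest.raises(BetaScanError, match="supply"):
            estimate_divergence_scalar(sites_at([1, 2, 3]), n=10)

    def test_divergence_recovery_on_simulated_genome(self):
        spec = NeutralGenSpec(theta_bp=0.006, span=200000, n=20, C=7.5, seed=17)
        sites = gen_neutral(spec)
        assert len(sites) > 10000
        assert estimate_divergence_scalar(sites, n=20) == pytest.approx(7.5, rel=0.05)


class TestScan:
    def test_empty_input_gives_empty_output(self):
        assert scan([], ScanConfig(statistic="B1")) == []

    def test_rows_are_position_sorted_and_standardized(self):
        sites = gen_neutral(NeutralGenSpec(theta_bp=0.006, span=20000, n=10, C=12.0, seed=5))
        rows = scan(sites, ScanConfig(statistic="B2", theta=0.006, C=12.0))
        assert rows
        positions = [r.position for r in rows]
        assert positions == sorted(positions)
        for r in rows:
            assert r.variance > 0
            assert r.beta_std == pytest.approx(r.beta / np.sqrt(r.variance))

    def test_global_position_shift_leaves_scores_unchanged(self):
        sites = gen_neutral(NeutralGenSpec(theta_bp=0.006, span=10000, n=10, C=12.0, seed=6))
        shifted = [
            SiteRecord(r.position + 77777, r.count, r.n) for r in sites
        ]
        config = ScanConfig(statistic="B2", theta=0.006, C=12.0)
        a, b = scan(sites, config), scan(shifted, config)
        assert [(r.beta, r.variance) for r in a] == [(r.beta, r.variance) for r in b]

    def test_b2_rejects_folded_input(self):
        folded = read_sites(["100\t2\t10", "200\t5\t10"], folded=True)
        with pytest.raises(BetaScanError):
            scan(folded, ScanConfig(statistic="B2", theta=0.01, C=5.0))

    def test_b1star_requires_folded_input(self):
        sites = sites_at([100, 200])
        with pytest.raises(BetaScanError):
            scan(sites, ScanConfig(statistic="B1star", theta=0.01))

    def test_estimated_nuisance_parameters_fill_in(self):
        sites = gen_neutral(NeutralGenSpec(theta_bp=0.006, span=50000, n=10, C=12.0, seed=7))
        rows = scan(sites, ScanConfig(statistic="B2"))  # theta and C estimated
        assert rows and all(r.variance > 0 for r in rows)


class TestLocusMode:
    def make_sites(self):
        return [
            SiteRecord(100, 5, 10),
            SiteRecord(150, 5, 10),
            SiteRecord(220, 2, 10),
            SiteRecord(300, 10, 10),
        ]

    def test_modal_core_frequency_default(self):
        row = score_locus(
            self.make_sites(), 50, 350,
            ScanConfig(statistic="B2", theta=0.01, C=8.0),
        )
        assert row.position == 200
        assert row.variance > 0

    def test_explicit_core_frequency_changes_score(self):
        config = ScanConfig(statistic="B2", theta=0.01, C=8.0)
        a = score_locus(self.make_sites(), 50, 350, config, core_freq=0.5)
        b = score_locus(self.make_sites(), 50, 350, config, core_freq=0.2)
        assert a.beta != b.beta

    def test_empty_interval_rejected(self):
        with pytest.raises(BetaScanError):
            score_locus(self.make_sites(), 300, 300, ScanConfig(statistic="B1", theta=0.01))

    def test_locus_without_snps_rejected(self):
        with pytest.raises(BetaScanError):
            score_locus(self.make_sites(), 1000, 2000, ScanConfig(statistic="B1", theta=0.01))


class TestPercentiles:
    def test_midrank_tie_handling(self):
        pct = empirical_percentiles([1.0, 2.0, 2.0, 5.0])
        assert pct == pytest.approx([0.25, 0.625, 0.625, 1.0])

    def test_attach_percentiles_orders_by_beta_std(self):
        sites = gen_neutral(NeutralGenSpec(theta_bp=0.006, span=20000, n=10, C=12.0, seed=8))
        rows = attach_percentiles(scan(sites, ScanConfig(statistic="B1", theta=0.006)))
        best = max(rows, key=lambda r: r.beta_std)
        assert best.percentile == max(r.percentile for r in rows)
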