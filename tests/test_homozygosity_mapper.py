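"""Window construction, scoring, zygosity calls and region merging."""

import numpy as np
import pytest

from enumapper.homozygosity_mapper import (
    Window,
    WindowConfig,
    call_zygosity,
    find_regions,
    make_windows,
    plot_tracks,
    score_windows,
)
from enumapper.variant_model import GenomeLayout

from conftest import make_variant

MB = 1_000_000


class TestCallZygosity:
    @pytest.mark.parametrize(
        "naf_pair,expected",
        [((10, 10), "hom"), ((5, 10), "het"), ((9, 10), "hom"), ((17, 20), "het")],
    )
    def test_threshold_at_0_9_boundary_inclusive(self, naf_pair, expected):
        alt, depth = naf_pair
        v = make_variant(depth=depth, alt_depth=alt)
        assert call_zygosity(v, 0.9) == expected

    def test_zero_depth_is_an_error(self):
        with pytest.raises(ValueError):
            call_zygosity(make_variant(depth=0, alt_depth=0), 0.9)


class TestMakeWindows:
    def test_50mb_chromosome_default_grid(self):
        layout = GenomeLayout((("1", 50 * MB),))
        wins = make_windows(layout, WindowConfig(size=20 * MB, step=1 * MB))
        assert len(wins) == 31  # floor((50-20)/1) + 1
        assert (wins[0].start, wins[0].end) == (0, 20 * MB)
        assert (wins[-1].start, wins[-1].end) == (30 * MB, 50 * MB)

    def test_window_size_equal_to_length(self):
        layout = GenomeLayout((("1", 20 * MB),))
        wins = make_windows(layout, WindowConfig(size=20 * MB, step=1 * MB))
        assert [(w.start, w.end) for w in wins] == [(0, 20 * MB)]

    def test_short_chromosome_single_window(self):
        layout = GenomeLayout((("1", 500_000),))
        wins = make_windows(layout, WindowConfig(size=20 * MB, step=1 * MB))
        assert [(w.start, w.end) for w in wins] == [(0, 500_000)]

    def test_sex_chromosomes_excluded(self, layout):
        wins = make_windows(layout, WindowConfig())
        assert {w.chrom for w in wins} == {"1", "2", "3"}

    def test_every_bp_covered_on_random_layouts(self, rng):
        for _ in range(10):
            length = int(rng.integers(1 * MB, 95 * MB))
            size = int(rng.integers(1, 25)) * MB
            step = int(rng.integers(1, size // MB + 1)) * MB
            layout = GenomeLayout((("1", length),))
            wins = make_windows(layout, WindowConfig(size=size, step=step))
            covered_until = 0
            for w in sorted(wins, key=lambda w: w.start):
                assert w.start <= covered_until  # no gap
                covered_until = max(covered_until, w.end)
            assert covered_until == length


class TestScoreWindows:
    def test_all_hom_window(self):
        layout = GenomeLayout((("1", 20 * MB),))
        wins = make_windows(layout, WindowConfig(size=20 * MB))
        vs = [make_variant("1", (i + 1) * MB, depth=10, alt_depth=10) for i in range(4)]
        scored = score_windows(vs, wins)
        assert scored[0].n_snps == 4
        assert scored[0].hom_count == 4
        assert scored[0].hom_pct == 100.0
        assert scored[0].avg_naf == pytest.approx(1.0)

    def test_hand_computed_mixture(self):
        layout = GenomeLayout((("1", 20 * MB),))
        wins = make_windows(layout, WindowConfig(size=20 * MB))
        nafs = [(10, 10), (10, 10), (5, 10), (5, 10)]
        vs = [
            make_variant("1", (i + 1) * MB, depth=d, alt_depth=a)
            for i, (a, d) in enumerate(nafs)
        ]
        scored = score_windows(vs, wins)
        assert scored[0].hom_count == 2
        assert scored[0].hom_pct == pytest.approx(50.0)
        assert scored[0].avg_naf == pytest.approx(0.75)

    def test_empty_window_metrics_undefined(self):
        layout = GenomeLayout((("1", 20 * MB),))
        scored = score_windows([], make_windows(layout, WindowConfig(size=20 * MB)))
        assert scored[0].n_snps == 0
        assert scored[0].hom_pct is None and scored[0].avg_naf is None

    def test_matches_naive_rescan_on_random_instances(self, rng):
        """Difference-array scoring equals a per-window linear rescan."""
        for rep in range(5):
            length = int(rng.integers(10 * MB, 60 * MB))
            layout = GenomeLayout((("1", length), ("2", length // 2)))
            cfg = WindowConfig(size=int(rng.integers(2, 12)) * MB, step=1 * MB)
            vs = []
            for chrom, chrom_len in layout.chromosomes:
                for pos in rng.integers(1, chrom_len + 1, size=1000).tolist():
                    d = int(rng.integers(5, 30))
                    a = int(rng.integers(0, d + 1))
                    vs.append(make_variant(chrom, pos, depth=d, alt_depth=a))
            wins = make_windows(layout, cfg)
            scored = score_windows(vs, wins, cfg)
            for w in scored:
                inside = [v for v in vs
                          if v.chrom == w.chrom and w.start <= v.pos0 < w.end]
                assert w.n_snps == len(inside)
                if inside:
                    hom = sum(1 for v in inside if v.naf >= cfg.hom_naf_threshold)
                    assert w.hom_count == hom
                    assert w.hom_pct == pytest.approx(100 * hom / len(inside))
                    assert w.avg_naf == pytest.approx(
                        sum(v.naf for v in inside) / len(inside))

    def test_snp_window_incidence_conserved(self, rng):
        """Sum of per-window counts equals sum over variants of the number
        of windows containing each."""
        layout = GenomeLayout((("1", 30 * MB),))
        cfg = WindowConfig(size=5 * MB, step=2 * MB)
        vs = [make_variant("1", int(p), depth=10, alt_depth=10)
              for p in rng.integers(1, 30 * MB + 1, size=500)]
        wins = score_windows(vs, make_windows(layout, cfg), cfg)
        total = sum(w.n_snps for w in wins)
        per_variant = sum(
            sum(1 for w in wins if w.start <= v.pos0 < w.end) for v in vs
        )
        assert total == per_variant


class TestFindRegions:
    def _windows(self, values, chrom="1", n_snps=10, size=20 * MB, step=1 * MB,
                 metric="avg_naf"):
        wins = []
        for i, val in enumerate(values):
            w = Window(chrom=chrom, start=i * step, end=i * step + size,
                       n_snps=n_snps, hom_count=0)
            if metric == "avg_naf":
                w.avg_naf = val
                w.hom_pct = 0.0
            else:
                w.hom_pct = val
                w.avg_naf = 0.0
            wins.append(w)
        return wins

    def test_background_naf_yields_no_regions(self):
        wins = self._windows([0.5] * 40)
        assert find_regions(wins, "naf", 0.7) == []

    def test_six_qualifying_windows_merge_to_25mb(self):
        vals = [0.5] * 5 + [0.95] * 6 + [0.5] * 5
        regions = find_regions(self._windows(vals), "naf", 0.7)
        assert len(regions) == 1
        r = regions[0]
        assert r.end - r.start == 25 * MB  # 20 Mb window + 5 x 1 Mb steps
        assert r.n_windows == 6
        assert r.peak_value == pytest.approx(0.95)

    def test_threshold_is_strict(self):
        wins = self._windows([0.7] * 6)
        assert find_regions(wins, "naf", 0.7) == []
        wins = self._windows([0.700001] * 6)
        assert len(find_regions(wins, "naf", 0.7)) == 1

    def test_min_snps_guard(self):
        wins = self._windows([0.95] * 6, n_snps=4)
        assert find_regions(wins, "naf", 0.7, WindowConfig(min_snps=5)) == []

    def test_homozygosity_criterion_uses_hom_pct(self):
        wins = self._windows([95.0] * 6, metric="hom_pct")
        regions = find_regions(wins, "homozygosity", 90.0)
        assert len(regions) == 1 and regions[0].criterion == "homozygosity"

    def test_regions_sorted_by_peak_then_genome_order(self):
        wins = (self._windows([0.8] * 3, chrom="1")
                + self._windows([0.95] * 3, chrom="2"))
        regions = find_regions(wins, "naf", 0.7)
        assert [r.chrom for r in regions] == ["2", "1"]

    def test_raising_threshold_never_expands_span(self, rng):
        vals = rng.uniform(0.3, 1.0, size=60).tolist()
        wins = self._windows(vals)
        spans = []
        for thr in (0.5, 0.7, 0.9):
            regions = find_regions(wins, "naf", thr)
            spans.append(sum(r.end - r.start for r in regions))
        assert spans == sorted(spans, reverse=True)


class TestPlotTracks:
    def test_empty_windows_no_crash(self, layout, tmp_path):
        out = tmp_path / "empty.png"
        meta = plot_tracks([], layout, out)
        assert out.exists() and out.stat().st_size > 0
        assert meta["n_windows_plotted"] == 0

    def test_spiked_chromosome_is_the_peak(self, layout, rng, tmp_path):
        cfg = WindowConfig(size=5 * MB, step=1 * MB)
        vs = []
        for chrom in ("1", "2", "3"):
            for pos in rng.integers(1, 50 * MB, size=300).tolist():
                d = int(rng.integers(5, 25))
                hom = chrom == "2" and 20 * MB < pos < 30 * MB
                a = d if hom else int(rng.integers(0, d + 1) * 0.6)
                vs.append(make_variant(chrom, pos, depth=d, alt_depth=min(a, d)))
        wins = score_windows(vs, make_windows(layout, cfg), cfg)
        meta = plot_tracks(wins, layout, tmp_path / "tracks.png")
        assert meta["peak_chrom"]["avg_naf"] == "2"
        assert meta["peak_chrom"]["hom_pct"] == "2"
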