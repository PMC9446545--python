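"""Loss/retention classification rules, promoter annotation and the report."""

import numpy as np
import pandas as pd
import pytest

from zcwcross import (
    ClassificationReport,
    GenomeLayout,
    Interval,
    PeakSet,
    SignalTrack,
    annotate_promoters,
    classify_atac_loss,
    classify_h3k9ac_loss,
    find_open_sites,
    joint_loss,
    mark_h3k9ac,
    summarize,
)
from zcwcross.classify import percent

LAYOUT = GenomeLayout(("chr1",), (100_000,))


def const_signal(value: float) -> SignalTrack:
    return SignalTrack("t", "", LAYOUT, {"chr1": np.full(100_000, float(value))})


def peaks(*ivs) -> PeakSet:
    return PeakSet.from_intervals([Interval("chr1", s, e) for s, e in ivs], layout=LAYOUT)


class TestMarking:
    def test_one_bp_overlap_is_marked(self):
        z = peaks((100, 300))
        h = peaks((299, 400))
        assert len(mark_h3k9ac(z, h)) == 1

    def test_abutting_is_unmarked(self):
        assert len(mark_h3k9ac(peaks((100, 300)), peaks((300, 400)))) == 0


class TestOpenSites:
    def test_twenty_percent_boundary_is_inclusive(self):
        z = peaks((0, 1000))
        atac = peaks((800, 1800))  # overlap 200 = exactly 20% of the 1000-bp ATAC peak
        assert len(find_open_sites(z, atac)) == 1

    def test_below_twenty_percent_is_closed(self):
        z = peaks((0, 100))
        atac = peaks((50, 1050))  # overlap 50 = 5% of 1000
        assert len(find_open_sites(z, atac)) == 0

    def test_fraction_of_site_mode(self):
        z = peaks((0, 100))
        atac = peaks((50, 1050))  # 50% of the 100-bp site
        assert len(find_open_sites(z, atac, fraction_of="site")) == 1


class TestAtacLoss:
    @pytest.mark.parametrize(
        "wt, ko, expect_lost",
        [
            (4.0, 1.0, True),   # ratio 4
            (2.0, 1.5, False),  # ratio < 2
            (2.0, 1.0, True),   # "at least 2-fold" is inclusive (pseudocount-adjusted)
        ],
    )
    def test_ratio_rule(self, wt, ko, expect_lost):
        sites = peaks((1000, 2000))
        # exact 2.0 ratio requires compensating the 0.01 denominator pseudocount
        ko_adj = wt / 2 - 0.01 if wt / ko == 2.0 else ko
        a1, a2 = classify_atac_loss(sites, const_signal(wt), const_signal(ko_adj))
        assert (len(a1), len(a2)) == ((1, 0) if expect_lost else (0, 1))

    def test_raising_threshold_never_grows_a1(self):
        sites = peaks((0, 100), (200, 300), (400, 500))
        rng = np.random.default_rng(5)
        wt = SignalTrack("a", "", LAYOUT, {"chr1": rng.uniform(1, 6, 100_000)})
        ko = const_signal(1.0)
        n2 = len(classify_atac_loss(sites, wt, ko, loss_ratio=2.0)[0])
        n3 = len(classify_atac_loss(sites, wt, ko, loss_ratio=3.0)[0])
        assert n3 <= n2


class TestH3k9acLoss:
    def test_no_ko_peak_means_lost(self):
        marked = peaks((1000, 2000))
        h1, h2 = classify_h3k9ac_loss(
            marked, peaks(), const_signal(1.0), const_signal(1.0)
        )
        assert len(h1) == 1 and len(h2) == 0

    def test_ko_peak_and_low_ratio_means_retained(self):
        marked = peaks((1000, 2000))
        h1, h2 = classify_h3k9ac_loss(
            marked, peaks((900, 2100)), const_signal(1.1), const_signal(1.0)
        )
        assert len(h1) == 0 and len(h2) == 1

    def test_ko_peak_but_high_ratio_means_lost(self):
        marked = peaks((1000, 2000))
        h1, h2 = classify_h3k9ac_loss(
            marked, peaks((900, 2100)), const_signal(5.0), const_signal(1.0)
        )
        assert len(h1) == 1

    def test_criteria_toggles(self):
        marked = peaks((1000, 2000))
        # ratio-only: no KO peak needed
        h1, h2 = classify_h3k9ac_loss(
            marked, None, const_signal(1.0), const_signal(1.0), require_ko_peak=False
        )
        assert len(h2) == 1
        # peak-only: high ratio ignored
        h1, h2 = classify_h3k9ac_loss(
            marked, peaks((900, 2100)), const_signal(9.0), const_signal(1.0),
            require_ratio=False,
        )
        assert len(h2) == 1


class TestJointLoss:
    def test_subset_gives_one(self):
        a1 = peaks((0, 100), (200, 300))
        h1 = peaks((0, 100), (200, 300), (400, 500))
        n, frac = joint_loss(a1, h1)
        assert (n, frac) == (2, 1.0)

    def test_disjoint_gives_zero(self):
        n, frac = joint_loss(peaks((0, 100)), peaks((200, 300)))
        assert (n, frac) == (0, 0.0)

    def test_printed_counts_round_to_84(self):
        assert percent(2250, 2676) == 84.0


class TestPromoters:
    TSS = [("chr1", 5000, "+"), ("chr1", 50_000, "-")]

    def test_site_containing_tss_is_promoter(self):
        flags = annotate_promoters(peaks((4900, 5100)), self.TSS)
        assert flags.tolist() == [True]

    def test_distant_site_is_not_promoter(self):
        flags = annotate_promoters(peaks((20_000, 20_500)), self.TSS)
        assert flags.tolist() == [False]

    def test_strand_aware_window(self):
        # '+' TSS at 5000 with window -2000/+500 covers [3000, 5500)
        assert annotate_promoters(peaks((3000, 3100)), self.TSS).tolist() == [True]
        assert annotate_promoters(peaks((5600, 5700)), self.TSS).tolist() == [False]
        # '-' TSS at 50_000 covers [49_500, 52_000)
        assert annotate_promoters(peaks((51_500, 51_600)), self.TSS).tolist() == [True]
        assert annotate_promoters(peaks((49_000, 49_400)), self.TSS).tolist() == [False]

    def test_empty_tss_list_rejected(self):
        with pytest.raises(ValueError):
            annotate_promoters(peaks((0, 100)), [])


def labels_frame(h_statuses, a_statuses, promoters=None):
    n = len(h_statuses)
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * n,
            "start": range(0, 1000 * n, 1000),
            "end": range(100, 1000 * n + 100, 1000),
            "h3k9ac_status": h_statuses,
            "atac_status": a_statuses,
            "promoter": promoters if promoters is not None else [False] * n,
        }
    )


class TestSummarize:
    def test_zero_sites_report_has_no_division_error(self):
        report = summarize(labels_frame([], []))
        assert report.n_sites == 0
        assert report.fractions["h1_percent"] == 0.0

    def test_counts_and_partition(self):
        labels = labels_frame(
            ["H1", "H1", "H2", "unmarked"], ["A1", "closed", "A2", "A1"]
        )
        report = summarize(labels)
        assert report.n_marked == 3 and report.n_h1 == 2 and report.n_h2 == 1
        assert report.n_open == 3 and report.n_a1 == 2 and report.n_a2 == 1
        assert report.n_joint == 1
        assert report.n_h1 + report.n_h2 == report.n_marked
        assert report.n_a1 + report.n_a2 == report.n_open

    def test_inconsistent_partition_rejected(self):
        with pytest.raises(ValueError):
            ClassificationReport(
                n_sites=10, n_marked=5, n_h1=2, n_h2=2, n_open=0, n_a1=0, n_a2=0, n_joint=0
            )

    def test_joint_exceeding_parent_rejected(self):
        with pytest.raises(ValueError):
            ClassificationReport(
                n_sites=10, n_marked=4, n_h1=2, n_h2=2, n_open=4, n_a1=2, n_a2=2, n_joint=3
            )


class TestPercentRounding:
    """Half-up rounding to the printed precision."""

    @pytest.mark.parametrize(
        "num, den, expected",
        [(4886, 6627, 74.0), (1741, 6627, 26.0), (2676, 4015, 67.0),
         (1339, 4015, 33.0), (2250, 2676, 84.0), (6627, 14688, 45.0)],
    )
    def test_integer_precision(self, num, den, expected):
        assert percent(num, den) == expected

    def test_one_decimal_precision(self):
        assert percent(734, 1000, 1) == 73.4
        assert percent(1, 3, 1) == 33.3

    def test_half_up(self):
        assert percent(1, 8, 1) == 12.5
        assert percent(25, 1000, 0) == 3.0  # 2.5 rounds up, not to even
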