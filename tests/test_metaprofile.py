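"""Metaprofile computations checked against per-base brute-force oracles on
toy genomes, plus strand handling and RPKM."""

import numpy as np
import pandas as pd
import pytest

from nucscreen import (
    CoverageTrack,
    GeneModel,
    aggregate_profile,
    filter_fragments,
    fragments_to_coverage,
    reference_point_matrix,
    rpkm,
    scale_regions_matrix,
)
from nucscreen.metaprofile import MalformedIntervalError


TOY = {"chrT": 10_000}


def toy_track(rng=None):
    if rng is None:
        return CoverageTrack({"chrT": np.full(10_000, 2.0)})
    return CoverageTrack({"chrT": rng.gamma(2.0, 1.5, 10_000)})


def padded(track, chrom, start, end):
    """Per-base window with explicit zero padding (oracle helper)."""
    out = np.zeros(end - start)
    arr = track.data[chrom]
    for i, g in enumerate(range(start, end)):
        if 0 <= g < len(arr):
            out[i] = arr[g]
    return out


def brute_reference_row(track, gene, up, down, bin_size):
    """Materialize the per-base oriented window, then average chunks."""
    if gene.strand == "+":
        win = padded(track, gene.chrom, gene.tss - up, gene.tss + down)
    else:
        win = padded(track, gene.chrom, gene.tss - down + 1, gene.tss + up + 1)[::-1]
    return [
        np.mean(win[i * bin_size : (i + 1) * bin_size])
        for i in range((up + down) // bin_size)
    ]


def brute_scale_row(track, gene, body_bins, flank, bin_size):
    body = padded(track, gene.chrom, gene.start, gene.end)
    if gene.strand == "+":
        up = padded(track, gene.chrom, gene.start - flank, gene.start)
        down = padded(track, gene.chrom, gene.end, gene.end + flank)
    else:
        body = body[::-1]
        up = padded(track, gene.chrom, gene.end, gene.end + flank)[::-1]
        down = padded(track, gene.chrom, gene.start - flank, gene.start)[::-1]
    L = len(body)
    chunks = [[] for _ in range(body_bins)]
    for j, v in enumerate(body):
        chunks[(j * body_bins) // L].append(v)
    row = [np.mean(up[i * bin_size : (i + 1) * bin_size]) for i in range(flank // bin_size)]
    row += [np.mean(c) for c in chunks]
    row += [np.mean(down[i * bin_size : (i + 1) * bin_size]) for i in range(flank // bin_size)]
    return row


class TestFilterFragments:
    def test_inclusive_bounds(self):
        frags = pd.DataFrame(
            {
                "chrom": "chrT",
                "start": [0, 0, 0, 0, 0],
                "end": [99, 100, 150, 200, 201],
            }
        )
        kept = filter_fragments(frags, 100, 200)
        assert list(kept["end"]) == [100, 150, 200]

    def test_empty(self):
        frags = pd.DataFrame({"chrom": [], "start": [], "end": []})
        assert len(filter_fragments(frags, 100, 200)) == 0

    def test_against_predicate_oracle(self, rng):
        starts = rng.integers(0, 5_000, 1_000)
        lengths = rng.integers(0, 400, 1_000)
        frags = pd.DataFrame({"chrom": "chrT", "start": starts, "end": starts + lengths})
        kept = filter_fragments(frags, 100, 200)
        expected = [i for i, L in enumerate(lengths) if 100 <= L <= 200]
        assert list(kept.index) == expected

    def test_negative_length_rejected(self):
        frags = pd.DataFrame({"chrom": ["chrT"], "start": [10], "end": [5]})
        with pytest.raises(MalformedIntervalError):
            filter_fragments(frags, 100, 200)


class TestFragmentsToCoverage:
    def test_single_and_stacked_intervals(self):
        frags = pd.DataFrame(
            {"chrom": ["chrT", "chrT", "chrT"], "start": [10, 30, 30], "end": [20, 40, 40]}
        )
        track = fragments_to_coverage(frags, TOY)
        arr = track.data["chrT"]
        assert (arr[10:20] == 1).all()
        assert (arr[30:40] == 2).all()
        assert arr.sum() == 30  # conservation: sum of fragment lengths

    def test_against_per_base_oracle(self, rng):
        starts = rng.integers(0, 9_000, 500)
        ends = starts + rng.integers(1, 300, 500)
        ends = np.minimum(ends, 10_000)
        frags = pd.DataFrame({"chrom": "chrT", "start": starts, "end": ends})
        track = fragments_to_coverage(frags, TOY)
        expected = np.zeros(10_000)
        for s, e in zip(starts, ends):
            expected[s:e] += 1
        np.testing.assert_array_equal(track.data["chrT"], expected)

    def test_out_of_bounds_rejected(self):
        frags = pd.DataFrame({"chrom": ["chrT"], "start": [9_990], "end": [10_050]})
        with pytest.raises(ValueError):
            fragments_to_coverage(frags, TOY)


class TestReferencePointMatrix:
    def test_flat_track(self):
        genes = [GeneModel("chrT", 4_000, 6_000, "+", "g1"),
                 GeneModel("chrT", 2_000, 3_000, "-", "g2")]
        m = reference_point_matrix(toy_track(), genes, 1_000, 1_000, 25)
        np.testing.assert_allclose(m.values, 2.0)

    def test_boxcar_hand_example(self):
        """Boxcar of height 10 on [TSS, TSS+100), bins of 25, window +/-50
        -> row [0, 0, 10, 10]."""
        arr = np.zeros(10_000)
        tss = 5_000
        arr[tss : tss + 100] = 10.0
        track = CoverageTrack({"chrT": arr})
        gene = GeneModel("chrT", tss, tss + 2_000, "+", "g1")
        m = reference_point_matrix(track, [gene], 50, 50, 25)
        np.testing.assert_allclose(m.values[0], [0, 0, 10, 10])

    def test_minus_strand_reflection(self):
        """The same boxcar placed 3' of a minus-strand TSS (genomic
        (TSS-100, TSS]) yields the identical row."""
        tss = 5_000
        arr = np.zeros(10_000)
        arr[tss - 99 : tss + 1] = 10.0
        track = CoverageTrack({"chrT": arr})
        gene = GeneModel("chrT", tss - 2_000, tss + 1, "-", "g1")
        assert gene.tss == tss
        m = reference_point_matrix(track, [gene], 50, 50, 25)
        np.testing.assert_allclose(m.values[0], [0, 0, 10, 10])

    def test_against_brute_force(self, rng):
        track = toy_track(rng)
        genes = [
            GeneModel("chrT", 3_000, 5_500, "+", "g1"),
            GeneModel("chrT", 6_000, 9_900, "-", "g2"),
            GeneModel("chrT", 100, 700, "+", "g3"),  # window over the edge
        ]
        m = reference_point_matrix(track, genes, 500, 1_000, 25)
        for row, gene in zip(m.values, genes):
            np.testing.assert_allclose(
                row, brute_reference_row(track, gene, 500, 1_000, 25), rtol=1e-12
            )

    def test_bad_bins(self):
        gene = GeneModel("chrT", 100, 200, "+", "g")
        with pytest.raises(ValueError):
            reference_point_matrix(toy_track(), [gene], 1_000, 1_000, 0)
        with pytest.raises(ValueError):
            reference_point_matrix(toy_track(), [gene], 1_010, 1_000, 25)


class TestScaleRegionsMatrix:
    def test_flat_track_any_length(self):
        genes = [GeneModel("chrT", 2_000, 2_777, "+", "g1"),
                 GeneModel("chrT", 4_000, 9_000, "-", "g2")]
        m = scale_regions_matrix(toy_track(), genes, 40, 1_000, 25)
        np.testing.assert_allclose(m.values, 2.0)

    def test_gradient_monotone_and_mirrored(self):
        arr = np.arange(10_000, dtype=float)
        track = CoverageTrack({"chrT": arr})
        plus = GeneModel("chrT", 2_000, 4_000, "+", "gp")
        minus = GeneModel("chrT", 2_000, 4_000, "-", "gm")
        m = scale_regions_matrix(track, [plus, minus], 20, 0, 25)
        assert (np.diff(m.values[0]) > 0).all()
        np.testing.assert_allclose(m.values[1], m.values[0][::-1])

    def test_short_gene_skipped(self):
        genes = [GeneModel("chrT", 100, 120, "+", "tiny"),
                 GeneModel("chrT", 2_000, 4_000, "+", "ok")]
        m = scale_regions_matrix(toy_track(), genes, 40, 0, 25)
        assert m.gene_ids == ["ok"]
        assert m.n_skipped == 1

    def test_against_brute_force(self, rng):
        track = toy_track(rng)
        genes = [
            GeneModel("chrT", 1_500, 3_777, "+", "g1"),
            GeneModel("chrT", 5_000, 9_321, "-", "g2"),
            GeneModel("chrT", 400, 1_300, "-", "g3"),
        ]
        m = scale_regions_matrix(track, genes, 30, 500, 25)
        for row, gene in zip(m.values, genes):
            np.testing.assert_allclose(
                row, brute_scale_row(track, gene, 30, 500, 25), rtol=1e-12
            )


class TestStrandInvolution:
    def test_reference_point(self, rng):
        """Flipping a gene's strand and mirroring the track around its TSS
        reproduces the row."""
        track = toy_track(rng)
        gene = GeneModel("chrT", 4_000, 6_000, "+", "g")
        tss = gene.tss
        mirrored = CoverageTrack(
            {"chrT": padded(track, "chrT", 2 * tss - 9_999, 2 * tss + 1)[::-1]}
        )
        flipped = GeneModel("chrT", 2 * tss - 5_999 + 0, tss + 1, "-", "g")
        # flipped gene's TSS (end-1) sits at the same coordinate
        assert flipped.tss == tss
        a = reference_point_matrix(track, [gene], 1_000, 1_000, 25).values
        b = reference_point_matrix(mirrored, [flipped], 1_000, 1_000, 25).values
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_scale_regions(self, rng):
        track = toy_track(rng)
        gene = GeneModel("chrT", 4_000, 6_000, "+", "g")
        # mirror genome around the gene's center so [start,end) maps onto itself
        c = gene.start + gene.end - 1
        mirrored = CoverageTrack(
            {"chrT": padded(track, "chrT", c - 9_999, c + 1)[::-1]}
        )
        flipped = GeneModel("chrT", 4_000, 6_000, "-", "g")
        a = scale_regions_matrix(track, [gene], 40, 1_000, 25).values
        b = scale_regions_matrix(mirrored, [flipped], 40, 1_000, 25).values
        np.testing.assert_allclose(a, b, rtol=1e-12)


class TestAggregateAndRpkm:
    def test_single_row_verbatim(self, rng):
        track = toy_track(rng)
        gene = GeneModel("chrT", 4_000, 6_000, "+", "g")
        m = reference_point_matrix(track, [gene], 500, 500, 25)
        np.testing.assert_array_equal(aggregate_profile(m), m.values[0])

    def test_symmetry(self):
        from nucscreen.metaprofile import ProfileMatrix

        m = ProfileMatrix(np.array([[0.0, 2.0], [2.0, 0.0]]), ["a", "b"], 25,
                          "reference_point_TSS", 25, 25)
        np.testing.assert_allclose(aggregate_profile(m), [1.0, 1.0])

    def test_against_column_mean_oracle(self, rng):
        from nucscreen.metaprofile import ProfileMatrix

        vals = rng.normal(size=(50, 20)) ** 2
        m = ProfileMatrix(vals, [f"g{i}" for i in range(50)], 25,
                          "reference_point_TSS", 250, 250)
        agg = aggregate_profile(m)
        for j in range(20):
            s = 0.0
            for i in range(50):
                s += vals[i, j]
            assert agg[j] == pytest.approx(s / 50, abs=1e-12)

    def test_empty_matrix_rejected(self):
        from nucscreen.metaprofile import ProfileMatrix

        m = ProfileMatrix(np.empty((0, 4)), [], 25, "scale_regions")
        with pytest.raises(ValueError):
            aggregate_profile(m)

    def test_rpkm_hand_examples(self):
        np.testing.assert_allclose(
            rpkm([10, 0, 1], [2_000, 500, 1_000], 1e6), [5.0, 0.0, 1.0]
        )

    def test_rpkm_domain_errors(self):
        with pytest.raises(ValueError):
            rpkm([1], [0], 1e6)
        with pytest.raises(ValueError):
            rpkm([1], [1_000], 0)

    def test_flat_track_conservation(self):
        """The aggregate of a flat-coverage track equals the track value in
        every bin."""
        genes = [GeneModel("chrT", 3_000, 5_000, "+", "g1"),
                 GeneModel("chrT", 6_000, 8_000, "-", "g2")]
        m = scale_regions_matrix(toy_track(), genes, 40, 1_000, 25)
        np.testing.assert_allclose(aggregate_profile(m), 2.0)
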