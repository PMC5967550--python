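"""Promoter windows, unique-read counting, RPKM, CAGE assignment and TMM."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from urnafate import expression as ex
from urnafate.io_formats import GenomicInterval, NcRnaLocus, ReadAlignmentRecord


def mklocus(start, end, strand="+", chrom="c", lid="x", family="U1"):
    return NcRnaLocus(
        interval=GenomicInterval(chrom, start, end, strand),
        species="sp",
        family=family,
        locus_id=lid,
    )


def mkread(rid, start, end, n_hits=1, sample="s1", chrom="c"):
    return ReadAlignmentRecord(
        read_id=rid,
        interval=GenomicInterval(chrom, start, end, "."),
        n_hits=n_hits,
        sample=sample,
    )


class TestPolIIWindow:
    def test_peak_covering_tss_in_all_lines(self):
        locus = mklocus(1000, 1150)
        peaks = {f"cl{i}": [GenomicInterval("c", 990, 1010)] for i in range(7)}
        rec = ex.classify_polii_support(locus, peaks)
        assert rec.category == ex.CATEGORY_ALL

    def test_exactly_500_bp_is_inclusive(self):
        locus = mklocus(1000, 1150)  # TSS at 1000
        peaks = {"cl0": [GenomicInterval("c", 300, 500)], "cl1": []}
        # nearest peak base is 499 -> distance 1000-499 = 501: outside
        rec = ex.classify_polii_support(locus, peaks)
        assert rec.category == ex.CATEGORY_NO_SITE
        peaks = {"cl0": [GenomicInterval("c", 300, 501)], "cl1": []}
        # nearest base 500 -> distance exactly 500: inside
        rec = ex.classify_polii_support(locus, peaks)
        assert rec.category == ex.CATEGORY_AT_LEAST_ONE

    def test_minus_strand_tss_is_right_end(self):
        locus = mklocus(1000, 1150, strand="-")  # TSS at 1149
        peaks = {"cl0": [GenomicInterval("c", 1600, 1650)]}
        rec = ex.classify_polii_support(locus, peaks)
        assert rec.per_cell_line["cl0"]  # 1600-1149 = 451 <= 500

    def test_empty_cell_line_map_rejected(self):
        with pytest.raises(ValueError):
            ex.classify_polii_support(mklocus(0, 10), {})

    def test_invariant_to_coordinate_shift_and_peak_order(self):
        locus = mklocus(5000, 5150)
        peaks = [GenomicInterval("c", 4400, 4600), GenomicInterval("c", 9000, 9100)]
        base = ex.classify_polii_support(locus, {"cl": peaks})
        shifted_locus = mklocus(15000, 15150)
        shifted = [GenomicInterval("c", iv.start + 10000, iv.end + 10000) for iv in peaks]
        assert (
            ex.classify_polii_support(shifted_locus, {"cl": shifted[::-1]}).category
            == base.category
        )


class TestUniqueCounting:
    LOCI = [mklocus(100, 200, lid="a"), mklocus(150, 250, lid="b"), mklocus(400, 500, lid="c")]

    def test_multimapped_read_not_counted_but_unique_library_size(self):
        reads = [mkread("r1", 410, 450, n_hits=2), mkread("r2", 420, 460)]
        counts, lib = ex.count_unique_reads(reads, self.LOCI)
        assert counts.loc["c", "s1"] == 1
        assert lib["s1"] == 1  # only the unique read

    def test_unique_read_over_two_loci_discarded(self):
        reads = [mkread("r1", 160, 190)]  # overlaps a and b
        counts, lib = ex.count_unique_reads(reads, self.LOCI)
        assert counts["s1"].sum() == 0
        assert lib["s1"] == 1  # still in the library

    def test_off_locus_unique_read_counts_toward_library_only(self):
        reads = [mkread("r1", 900, 950)]
        counts, lib = ex.count_unique_reads(reads, self.LOCI)
        assert counts["s1"].sum() == 0 and lib["s1"] == 1

    def test_counted_total_bounded_by_unique_total(self):
        rng = np.random.default_rng(2)
        reads = [
            mkread(f"r{i}", int(s), int(s) + 30, n_hits=int(h), sample=f"s{i%2}")
            for i, (s, h) in enumerate(
                zip(rng.integers(0, 600, 200), rng.choice([1, 1, 1, 2], 200))
            )
        ]
        counts, lib = ex.count_unique_reads(reads, self.LOCI)
        for s in counts.columns:
            assert counts[s].sum() <= lib[s]

    def test_bad_n_hits_rejected(self):
        with pytest.raises(Exception):
            mkread("r", 0, 10, n_hits=0)

    def test_simulator_truth_recovered_with_zero_noise(self, noise_free_dataset):
        """Counts equal the simulator's per-locus unique-read truth."""
        ds = noise_free_dataset
        sp = ds.species[0]
        counts, _ = ex.count_unique_reads(ds.reads[sp], ds.loci[sp])
        truth = {}
        for rec in ds.reads[sp]:
            if rec.n_hits != 1:
                continue
            for l in ds.loci[sp]:
                if l.interval.overlaps(rec.interval):
                    truth[(l.locus_id, rec.sample)] = truth.get((l.locus_id, rec.sample), 0) + 1
        for (lid, sample), n in truth.items():
            assert counts.loc[lid, sample] == n


class TestRpkm:
    @pytest.mark.parametrize(
        "count,lib,length,expected",
        [
            (1000, 1_000_000, 1000, 1000.0),
            (0, 1_000_000, 1000, 0.0),
            (5, 2_000_000, 150, (5 / 2) / 0.15),
        ],
    )
    def test_formula_identity(self, count, lib, length, expected):
        assert ex.rpkm(count, lib, length) == pytest.approx(expected)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            ex.rpkm(5, 0, 100)


class TestCageAssignment:
    def peak(self, start, end, strand, counts, chrom="c"):
        return ex.CagePeak(
            interval=GenomicInterval(chrom, start, end, strand), counts=counts
        )

    def test_opposite_strand_peak_unassigned(self):
        locus = mklocus(1000, 1150, "+")
        peak = self.peak(1000, 1020, "-", {"s1": 5})
        m = ex.assign_cage_peaks([peak], [locus])
        assert m.loc["x", "s1"] == 0

    def test_ambiguous_peak_dropped(self):
        loci = [mklocus(1000, 1150, "+", lid="a"), mklocus(1400, 1550, "+", lid="b")]
        peak = self.peak(1200, 1220, "+", {"s1": 5})  # within 500 of both 5' ends
        m = ex.assign_cage_peaks([peak], loci)
        assert m["s1"].sum() == 0

    def test_tag_counts_summed_per_locus(self):
        locus = mklocus(1000, 1150, "+")
        peaks = [
            self.peak(900, 920, "+", {"s1": 3}),
            self.peak(1100, 1120, "+", {"s1": 4}),
        ]
        m = ex.assign_cage_peaks(peaks, [locus])
        assert m.loc["x", "s1"] == 7

    def test_protein_coding_tss_exclusion_same_strand_only(self):
        locus = mklocus(1000, 1150, "+")
        peak = self.peak(900, 920, "+", {"s1": 5})
        assert (
            ex.assign_cage_peaks([peak], [locus], pc_tss=[("c", 850, "+")])["s1"].sum()
            == 0
        )
        # same position, opposite strand: not excluded
        assert (
            ex.assign_cage_peaks([peak], [locus], pc_tss=[("c", 850, "-")]).loc[
                "x", "s1"
            ]
            == 5
        )

    def test_minus_strand_five_prime_is_end_minus_one(self):
        locus = mklocus(1000, 1150, "-")  # 5' end at 1149
        peak = self.peak(1600, 1620, "-", {"s1": 2})  # 5' at 1619; |1619-1149|=470
        m = ex.assign_cage_peaks([peak], [locus])
        assert m.loc["x", "s1"] == 2

    def test_strandless_locus_rejected(self):
        with pytest.raises(ex.DataError):
            ex.assign_cage_peaks([], [mklocus(0, 10, ".")])


class TestCageFilter:
    def test_sparse_sample_then_sparse_locus_removed(self):
        m = pd.DataFrame(
            {"s1": [1, 1, 0], "s2": [1, 0, 1], "s3": [0, 0, 1]},
            index=["l1", "l2", "l3"],
        )
        out = ex.filter_cage_matrix(m)
        # s3 expresses only l3 -> dropped; then l2, l3 expressed in <2
        # remaining samples -> dropped
        assert list(out.columns) == ["s1", "s2"] and list(out.index) == ["l1"]

    def test_boundary_locus_in_exactly_two_samples_retained(self):
        m = pd.DataFrame({"s1": [1, 2], "s2": [1, 3], "s3": [0, 4]}, index=["l1", "l2"])
        out = ex.filter_cage_matrix(m)
        assert "l1" in out.index

    def test_fixpoint_differs_from_one_pass_on_crafted_matrix(self):
        m = pd.DataFrame(
            {"s1": [1, 1, 0], "s2": [1, 0, 1], "s3": [0, 0, 1]},
            index=["l1", "l2", "l3"],
        )
        one_pass = ex.filter_cage_matrix(m, iterate=False)
        fixpoint = ex.filter_cage_matrix(m, iterate=True)
        assert one_pass.shape == (1, 2)
        assert fixpoint.empty  # iterating removes everything here

    def test_empty_matrix_passes_through(self):
        m = pd.DataFrame()
        assert ex.filter_cage_matrix(m).empty


def tmm_oracle(matrix: pd.DataFrame, trim_m=0.30, trim_a=0.05):
    """Independent step-by-step TMM implementation (plain loops)."""
    lib = {s: float(matrix[s].sum()) for s in matrix.columns}
    f75 = {
        s: float(np.quantile(matrix[s].to_numpy(), 0.75)) / lib[s] for s in matrix.columns
    }
    mean75 = sum(f75.values()) / len(f75)
    ref = min(matrix.columns, key=lambda s: (abs(f75[s] - mean75), list(matrix.columns).index(s)))
    logf = {}
    for s in matrix.columns:
        if s == ref:
            logf[s] = 0.0
            continue
        ms, was, aas = [], [], []
        for lid in matrix.index:
            y, r = float(matrix.loc[lid, s]), float(matrix.loc[lid, ref])
            if y <= 0 or r <= 0:
                continue
            ms.append(np.log2((y / lib[s]) / (r / lib[ref])))
            aas.append(0.5 * np.log2((y / lib[s]) * (r / lib[ref])))
            was.append((lib[s] - y) / (lib[s] * y) + (lib[ref] - r) / (lib[ref] * r))
        ms, aas, was = map(np.asarray, (ms, aas, was))
        if ms.size == 0 or np.abs(ms).max() < 1e-10:
            logf[s] = 0.0
            continue
        n = ms.size
        rm, ra = rankdata(ms), rankdata(aas)
        lo_m, lo_a = np.floor(n * trim_m) + 1, np.floor(n * trim_a) + 1
        keep = (
            (rm >= lo_m) & (rm <= n + 1 - lo_m) & (ra >= lo_a) & (ra <= n + 1 - lo_a)
        )
        logf[s] = float(np.sum(ms[keep] / was[keep]) / np.sum(1.0 / was[keep]))
    mean_lf = sum(logf.values()) / len(logf)
    return {s: 2.0 ** (v - mean_lf) for s, v in logf.items()}


class TestTmm:
    def test_identical_samples_all_factors_one(self):
        m = pd.DataFrame({"a": [5, 10, 3], "b": [5, 10, 3], "c": [5, 10, 3]})
        f = ex.tmm_factors(m)
        assert all(v == pytest.approx(1.0) for v in f.factors.values())

    def test_pure_depth_scaling_absorbed_by_library_size(self):
        m = pd.DataFrame({"a": [10, 20, 30, 40], "b": [20, 40, 60, 80]})
        f = ex.tmm_factors(m)
        assert f.factors["a"] == pytest.approx(f.factors["b"])

    def test_geometric_mean_exactly_one(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.poisson(30, size=(40, 5)), columns=list("abcde"))
        f = ex.tmm_factors(m)
        logs = np.log([f.factors[s] for s in m.columns])
        assert logs.mean() == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_oracle_on_random_poisson(self):
        rng = np.random.default_rng(42)
        for rep in range(5):
            base = rng.gamma(2.0, 20.0, size=(50, 1))
            scale = rng.uniform(0.5, 2.0, size=4)
            m = pd.DataFrame(
                rng.poisson(base * scale, size=(50, 4)), columns=list("abcd")
            )
            if (m.sum(axis=0) == 0).any():
                continue
            mine = ex.tmm_factors(m).factors
            oracle = tmm_oracle(m)
            for s in m.columns:
                assert mine[s] == pytest.approx(oracle[s], abs=1e-8)

    def test_all_zero_sample_rejected(self):
        m = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ex.DataError, match="b"):
            ex.tmm_factors(m)

    def test_tpm_formula(self):
        m = pd.DataFrame({"a": [100, 900], "b": [300, 700]})
        f = ex.tmm_factors(m)
        tpm = ex.tmm_tpm(m, f)
        assert tpm.loc[0, "a"] == pytest.approx(
            100 / (f.factors["a"] * 1000) * 1e6
        )
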