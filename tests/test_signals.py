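"""Signal store, flank extraction, binning normalization, sequencing speed."""

import numpy as np
import pytest

from delsieve.reads import Allele, ReadGroupAssignment, Strand
from delsieve.signals import (
    MissingSegmentError,
    NotEvaluatedError,
    SignalStore,
    bin_normalize,
    build_matrix,
    extract_flank_signal,
    load_signal_store,
    load_tombo_fast5_dir,
    save_signal_store,
    sequencing_speed,
)
from delsieve.variants import FlankWindow


def _store_with_read(read_id="r1", positions=range(10, 22), per_base=4, base_val=None):
    store = SignalStore()
    current = []
    bounds = {}
    off = 0
    for p in positions:
        v = float(p if base_val is None else base_val)
        current.extend([v] * per_base)
        bounds[p] = (off, off + per_base)
        off += per_base
    store.add_read(read_id, np.array(current), bounds)
    return store


def _assignment(read_id, allele=Allele.NODEL):
    return ReadGroupAssignment(read_id=read_id, strand=Strand.FWD, allele=allele,
                               read_window=(), window_quals=())


WINDOW = FlankWindow(contig="c", left=(11, 12, 13, 14, 15), right=(17, 18, 19, 20, 21), k=5)


class TestStore:
    def test_tsv_round_trip(self, tmp_path):
        store = _store_with_read()
        path = tmp_path / "sig.tsv"
        save_signal_store(store, path)
        loaded = load_signal_store(path)
        assert set(loaded.signals) == {"r1"}
        for p in range(10, 22):
            np.testing.assert_allclose(loaded.segment("r1", p), store.segment("r1", p))

    def test_segment_lookup_and_missing_error(self):
        store = _store_with_read()
        assert store.segment("r1", 10).tolist() == [10.0] * 4
        with pytest.raises(MissingSegmentError):
            store.segment("r1", 99)
        with pytest.raises(MissingSegmentError):
            store.segment("nope", 10)

    def test_bounds_must_be_ordered_and_inside_signal(self):
        store = SignalStore()
        with pytest.raises(ValueError):
            store.add_read("bad", np.arange(4.0), {0: (0, 3), 1: (2, 4)})


class TestExtraction:
    def test_flank_concatenation_order_and_length(self):
        store = _store_with_read()
        sig = extract_flank_signal(store, _assignment("r1"), WINDOW)
        assert sig.size == 40  # 10 window bases x 4 samples
        # left flank values then right flank values, reference order
        assert sig[:4].tolist() == [11.0] * 4
        assert sig[-4:].tolist() == [21.0] * 4

    def test_deleted_base_contributes_nothing(self):
        # a DEL read has no segment at refpos 16; flank-only extraction works
        store = _store_with_read(positions=[p for p in range(10, 22) if p != 16])
        sig = extract_flank_signal(store, _assignment("r1", Allele.DEL), WINDOW)
        assert sig.size == 40

    def test_read_absent_from_store_raises(self):
        store = _store_with_read()
        with pytest.raises(MissingSegmentError):
            extract_flank_signal(store, _assignment("ghost"), WINDOW)


class TestBinNormalize:
    def test_exact_bin_alignment(self):
        x = np.repeat(np.arange(1.0, 11.0), 4)
        np.testing.assert_allclose(bin_normalize(x, 10), np.arange(1.0, 11.0))

    def test_identity_when_length_equals_bins(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        np.testing.assert_allclose(bin_normalize(x, 5), x)

    def test_boundary_rule_L10_B4(self):
        # bins cover [0,2) [2,5) [5,7) [7,10)
        x = np.arange(10.0)
        np.testing.assert_allclose(bin_normalize(x, 4), [0.5, 3.0, 5.5, 8.0])

    def test_mean_preserved_when_bins_divide_length(self):
        rng = np.random.default_rng(0)
        for B, mult in [(5, 4), (10, 3), (7, 2)]:
            x = rng.normal(size=B * mult)
            assert np.isclose(bin_normalize(x, B).mean(), x.mean())

    def test_stretch_invariance_on_exact_divisors(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        for k in (2, 3, 5):
            stretched = np.repeat(x, k)
            np.testing.assert_allclose(bin_normalize(stretched, 20), x)

    def test_monotone_input_bins_to_monotone_output(self):
        x = np.sort(np.random.default_rng(2).normal(size=53))
        out = bin_normalize(x, 10)
        assert np.all(np.diff(out) >= 0)

    def test_short_signal_carries_values_forward(self):
        out = bin_normalize(np.array([1.0, 2.0]), 5)
        # bins: [0,0) [0,0) [0,1) [1,1) [1,2) -> backfill, 1, carry, 2
        assert out.tolist() == [1.0, 1.0, 1.0, 1.0, 2.0]

    def test_empty_signal_is_an_error(self):
        with pytest.raises(ValueError):
            bin_normalize(np.array([]), 4)


class TestSequencingSpeed:
    def test_measurements_per_base(self):
        per_base, bps = sequencing_speed(40, 4)
        assert per_base == 10.0
        assert bps == 400.0  # 4 kHz sampler at 10 samples/base

    def test_single_measurement_single_base(self):
        assert sequencing_speed(1, 1)[0] == 1.0

    def test_zero_bases_is_an_error(self):
        with pytest.raises(ValueError):
            sequencing_speed(10, 0)


class TestBuildMatrix:
    def _reads(self, n_del=3, n_nodel=3):
        reads = []
        for i in range(n_del):
            reads.append(_assignment(f"d{i}", Allele.DEL))
        for i in range(n_nodel):
            reads.append(_assignment(f"n{i}", Allele.NODEL))
        return reads

    def _multi_store(self, ids):
        store = SignalStore()
        for rid in ids:
            sub = _store_with_read(rid)
            store.add_read(rid, sub.signals[rid], sub.bounds[rid])
        return store

    def test_shape_and_sorted_rows(self):
        reads = self._reads()
        store = self._multi_store([r.read_id for r in reads])
        m = build_matrix(store, reads, WINDOW, n_bins=20)
        assert m.values.shape == (6, 20)
        assert m.read_ids == sorted(m.read_ids)
        assert m.n_del == 3 and m.n_nodel == 3

    def test_missing_reads_are_dropped_with_counter(self):
        reads = self._reads()
        store = self._multi_store([r.read_id for r in reads if r.read_id != "d2"])
        m = build_matrix(store, reads, WINDOW, n_bins=20)
        assert m.n_dropped == 1
        assert m.n_del == 2

    def test_losing_a_whole_group_is_not_evaluated(self):
        reads = self._reads(n_del=2, n_nodel=2)
        store = self._multi_store(["n0", "n1"])  # all DEL reads missing
        with pytest.raises(NotEvaluatedError):
            build_matrix(store, reads, WINDOW, n_bins=20)


class TestFast5Adapter:
    def test_reads_tombo_layout(self, tmp_path):
        import h5py

        # synthetic single-read fast5 mimicking a resquiggled layout
        raw = np.arange(100, dtype=np.int16)
        events = np.zeros(8, dtype=[("start", "<i8"), ("length", "<i8"),
                                    ("norm_mean", "<f8"), ("base", "S1")])
        for i in range(8):
            events[i] = (i * 10, 10, 0.0, b"A")
        with h5py.File(tmp_path / "read0.fast5", "w") as f5:
            grp = f5.create_group("Raw/Reads/Read_7")
            grp.create_dataset("Signal", data=raw)
            grp.attrs["read_id"] = b"readX"
            bc = f5.create_group("Analyses/RawGenomeCorrected_000/BaseCalled_template")
            bc.attrs["shift"] = 10.0
            bc.attrs["scale"] = 2.0
            ev = bc.create_dataset("Events", data=events)
            ev.attrs["read_start_rel_to_raw"] = 20
            aln = bc.create_group("Alignment")
            aln.attrs["mapped_start"] = 1000
            aln.attrs["mapped_chrom"] = "chr1"
            aln.attrs["mapped_strand"] = "+"
        store = load_tombo_fast5_dir(tmp_path)
        assert "readX" in store
        seg = store.segment("readX", 1000)
        np.testing.assert_allclose(seg, (raw[20:30] - 10.0) / 2.0)
        assert store.covered_positions("readX") == list(range(1000, 1008))
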