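"""Synthetic library / selection / FACS generators and their ground truth."""

import numpy as np
import pytest

from dmsflow.io import count_fastq_file
from dmsflow.synthetic import (
    FacsSpec,
    LibrarySpec,
    SelectionSpec,
    bin_assignment_probabilities,
    expected_frequencies,
    make_library,
    simulate_facs,
    simulate_selection,
    write_fastq_fixture,
)
from dmsflow.variants import ReferenceSpec, call_dna_variant

REF = "ATGAAAGGGTTTCCCATCGATTGA"


class TestMakeLibrary:
    def test_single_wt_variant(self):
        lib = make_library(
            LibrarySpec(1, 8, REF, substitutions_per_variant=0, seed=1)
        )
        assert len(lib.variants) == 1
        assert lib.variants[0].sequence == REF
        assert lib.variants[0].hgvs_dna == "c.="

    def test_barcode_cardinality(self):
        lib = make_library(LibrarySpec(3, 8, REF, barcodes_per_variant=2, seed=2))
        barcodes = [bc for v in lib.variants for bc in v.barcodes]
        assert len(barcodes) == 6 and len(set(barcodes)) == 6
        assert lib.barcode_map.n_rows == 6

    def test_seed_determinism_and_distinct_seeds(self):
        a = make_library(LibrarySpec(5, 8, REF, seed=3))
        b = make_library(LibrarySpec(5, 8, REF, seed=3))
        c = make_library(LibrarySpec(5, 8, REF, seed=4))
        assert [v.sequence for v in a.variants] == [v.sequence for v in b.variants]
        assert a.barcode_map.equals(b.barcode_map)
        assert [v.sequence for v in a.variants] != [v.sequence for v in c.variants]

    def test_truth_hgvs_matches_independent_caller(self):
        """The generator builds hgvs positionally; the caller must agree."""
        lib = make_library(LibrarySpec(20, 8, REF, substitutions_per_variant=2, seed=5))
        ref = ReferenceSpec(REF)
        for v in lib.variants:
            assert call_dna_variant(v.sequence, ref).hgvs_dna == v.hgvs_dna

    def test_variant_sequences_distinct(self):
        lib = make_library(LibrarySpec(50, 8, REF, substitutions_per_variant=1, seed=6))
        seqs = [v.sequence for v in lib.variants]
        assert len(set(seqs)) == len(seqs)

    def test_infeasible_barcode_space_rejected(self):
        with pytest.raises(ValueError):
            LibrarySpec(300, 4, REF)  # 4^4=256 < 300


class TestSimulateSelection:
    def _lib(self, n=4, seed=0):
        return make_library(
            LibrarySpec(n, 8, REF, include_wt=True, seed=seed)
        )

    def test_counts_sum_to_depth_exactly(self):
        lib = self._lib()
        sel = SelectionSpec((0.0, 1.0, -1.0, 0.5), depth=5000, replicates=2, seed=1)
        t = simulate_selection(lib, sel).df
        totals = t.groupby(["replicate", "time"])["count"].sum()
        assert (totals == 5000).all()

    def test_neutral_selection_flat_expected_frequencies(self):
        sel = SelectionSpec((0.0, 0.0, 0.0), times=(0, 1, 2), seed=0)
        f = expected_frequencies(sel)
        assert np.allclose(f, 1 / 3)

    def test_expected_enrichment_ratio_at_high_depth(self):
        """s=(0, ln4) with equal start: 1:4 count ratio at the last time."""
        lib = self._lib(n=2)
        sel = SelectionSpec(
            (0.0, float(np.log(4))),
            times=(0.0, 1.0),
            depth=1_000_000,
            replicates=1,
            seed=7,
        )
        t = simulate_selection(lib, sel).df
        final = t[t["time"] == 1.0]
        bc_to_variant = {
            bc: i for i, v in enumerate(lib.variants) for bc in v.barcodes
        }
        counts = [0, 0]
        for bc, c in zip(final["barcode"], final["count"]):
            counts[bc_to_variant[str(bc)]] += int(c)
        p = 4 / 5  # expected share of the enriched variant
        sigma = np.sqrt(1_000_000 * p * (1 - p))
        assert abs(counts[1] - 1_000_000 * p) < 3 * sigma

    def test_seed_determinism(self):
        lib = self._lib()
        sel = SelectionSpec((0.0, 1.0, -1.0, 0.5), depth=2000, seed=9)
        assert simulate_selection(lib, sel).equals(simulate_selection(lib, sel))


class TestSimulateFacs:
    def test_degenerate_sorting_tops_bin(self):
        lib = make_library(LibrarySpec(2, 8, REF, seed=1))
        spec = FacsSpec((1.0, 1.0), n_bins=4, spillover=0.0, depth_per_bin=100, seed=2)
        t = simulate_facs(lib, spec).df
        assert set(t["bin"].unique()) == {4}

    def test_assignment_probabilities_sum_to_one(self):
        spec = FacsSpec(tuple(np.linspace(0, 1, 11)), n_bins=4, spillover=0.2)
        probs = bin_assignment_probabilities(spec)
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_spillover_bounds(self):
        with pytest.raises(ValueError):
            FacsSpec((0.5,), spillover=0.5)

    def test_mean_bin_matches_expectation_model(self):
        """Uniform theta, no spillover: mean assigned bin tracks the oracle
        expectation computed directly from the assignment rule."""
        theta = tuple(np.linspace(0.01, 0.99, 50))
        spec = FacsSpec(theta, n_bins=4, spillover=0.0, depth_per_bin=200_000, seed=3)
        probs = bin_assignment_probabilities(spec)
        oracle_primary = np.clip(np.ceil(np.array(theta) * 4), 1, 4)
        got_primary = probs.argmax(axis=1) + 1
        assert np.array_equal(got_primary, oracle_primary)

    def test_seed_determinism(self):
        lib = make_library(LibrarySpec(3, 8, REF, seed=4))
        spec = FacsSpec((0.1, 0.5, 0.9), seed=5)
        assert simulate_facs(lib, spec).equals(simulate_facs(lib, spec))


class TestWriteFastqFixture:
    def test_round_trip_recovers_counts(self, tmp_path):
        lib = make_library(LibrarySpec(5, 8, REF, include_wt=True, seed=11))
        sel = SelectionSpec((0.0, 0.5, -0.5, 1.0, -1.0), depth=3000, replicates=1, seed=12)
        counts = simulate_selection(lib, sel)
        paths = write_fastq_fixture(counts, tmp_path)
        assert len(paths) == len(sel.times)
        df = counts.df
        for p in paths:
            table, tally = count_fastq_file(p)
            # recover the (replicate, time) group from the file name
            import re

            m = re.match(r"sim_rep(\d+)_t(\d+)\.fastq", p.name)
            rep, t = int(m.group(1)), float(m.group(2))
            sub = df[(df["replicate"] == rep) & (df["time"] == t) & (df["count"] > 0)]
            expected = dict(zip(sub["barcode"], sub["count"]))
            got = dict(zip(table.df["sequence"], table.df["count"]))
            assert got == expected
            assert tally.records_read == sum(expected.values())

    def test_zero_count_barcodes_absent(self, tmp_path):
        import pandas as pd

        from dmsflow.table import Table

        counts = Table(
            pd.DataFrame({"barcode": ["AAAA", "CCCC"], "count": [2, 0]})
        )
        paths = write_fastq_fixture(
            counts, tmp_path, name_template="x.fastq", group_cols=()
        )
        text = paths[0].read_text()
        assert text.count("AAAA") == 2 and "CCCC" not in text

    def test_gzip_output_seed_stable_bytes(self, tmp_path):
        import pandas as pd

        from dmsflow.table import Table

        counts = Table(pd.DataFrame({"barcode": ["ACGT"], "count": [3]}))
        p1 = write_fastq_fixture(
            counts, tmp_path / "a", name_template="x.fastq", group_cols=(), compress=True
        )[0]
        p2 = write_fastq_fixture(
            counts, tmp_path / "b", name_template="x.fastq", group_cols=(), compress=True
        )[0]
        assert p1.read_bytes() == p2.read_bytes()
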