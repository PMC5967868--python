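"""I/O layer: BED/narrowPeak, FASTA, bedGraph and DE-table round trips."""

import gzip

import numpy as np
import pandas as pd
import pytest

from grbs import (
    PeakSet,
    read_bed,
    read_bedgraph,
    read_de_table,
    read_fasta,
    write_bed,
    write_bedgraph,
    write_de_table,
)
from grbs.formats import FormatError, Genome, write_fasta
from grbs.signal import CoverageTrack

from oracles import random_intervals


class TestBed:
    def test_three_column_defaults(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        (iv,) = read_bed(p)
        assert (iv.chrom, iv.start, iv.end) == ("chr1", 100, 200)
        assert (iv.name, iv.score, iv.strand, iv.summit_offset) == (".", 0.0, ".", None)

    def test_narrowpeak_summit(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t100\t200\tpk\t5\t+\t1.0\t2.0\t3.0\t50\n"
                     "chr1\t300\t400\tpk2\t5\t+\t1.0\t2.0\t3.0\t-1\n")
        ps = read_bed(p, format_hint="narrowpeak")
        assert ps[0].summit_offset == 50 and ps[0].anchor == 150
        assert ps[1].summit_offset is None and ps[1].anchor == 350

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t200\nchr1\t500\t400\n")
        with pytest.raises(FormatError, match=":2:"):
            read_bed(p)

    def test_non_integer_coordinates_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\tx\t200\n")
        with pytest.raises(FormatError, match="non-integer"):
            read_bed(p)

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            ps = read_bed(p)
        assert len(ps) == 0

    def test_track_lines_skipped(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("track name=x\nchr1\t1\t2\n")
        assert len(read_bed(p)) == 1

    def test_sorting_matches_independent_sort(self, tmp_path, rng):
        ivs = random_intervals(rng, 1000)
        p = tmp_path / "r.bed"
        write_bed(PeakSet("r", []), p)  # truncate
        with open(p, "w") as fh:
            for iv in ivs:  # deliberately unsorted write
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t.\n")
        ps = read_bed(p)
        expected = sorted(ivs, key=lambda iv: (iv.chrom, iv.start, iv.end))
        assert [(i.chrom, i.start, i.end) for i in ps] == [
            (i.chrom, i.start, i.end) for i in expected
        ]

    def test_round_trip_identity(self, tmp_path, rng):
        ps = PeakSet("x", random_intervals(rng, 200))
        p = tmp_path / "x.bed"
        write_bed(ps, p)
        back = read_bed(p, label="x")
        for a, b in zip(ps, back):
            assert (a.chrom, a.start, a.end, a.name, a.score, a.strand) == (
                b.chrom, b.start, b.end, b.name, b.score, b.strand
            )

    def test_gzip_transparent(self, tmp_path):
        p = tmp_path / "a.bed.gz"
        with gzip.open(p, "wt") as fh:
            fh.write("chr1\t5\t10\n")
        assert len(read_bed(p)) == 1


class TestFasta:
    def test_case_fold_and_alphabet(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nacgt\n>c2\nACRT\n")
        with pytest.warns(UserWarning, match="1 non-ACGTN"):
            g = read_fasta(p)
        assert g.sequences["chr1"] == "ACGT"
        assert g.sequences["c2"] == "ACNT"

    def test_duplicate_header_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nACGT\n>chr1\nTTTT\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_fasta(p)

    def test_multi_record_lengths(self, tmp_path, rng):
        seqs = {f"chr{i}": "".join(rng.choice(list("ACGT"), size=n))
                for i, n in enumerate([37, 160, 81], start=1)}
        p = tmp_path / "g.fa"
        write_fasta(Genome(seqs), p, line_width=50)
        g = read_fasta(p)
        assert g.lengths == {c: len(s) for c, s in seqs.items()}
        assert g.sequences == seqs


class TestBedgraph:
    def test_uncovered_bases_zero_and_mean(self, tmp_path):
        p = tmp_path / "t.bg"
        p.write_text("chr1\t0\t10\t2.5\n")
        t = read_bedgraph(p, {"chr1": 20})
        assert t.chrom_values("chr1").mean() == pytest.approx(1.25)

    def test_half_open_adjacent_runs(self, tmp_path):
        p = tmp_path / "t.bg"
        p.write_text("chr1\t0\t10\t1\nchr1\t10\t20\t3\n")
        t = read_bedgraph(p, {"chr1": 20})
        assert t.chrom_values("chr1")[10] == 3

    def test_overlap_rejected(self, tmp_path):
        p = tmp_path / "t.bg"
        p.write_text("chr1\t0\t10\t1\nchr1\t5\t15\t2\n")
        with pytest.raises(FormatError, match="overlapping"):
            read_bedgraph(p, {"chr1": 20})

    def test_unknown_chrom_and_out_of_bounds(self, tmp_path):
        p = tmp_path / "t.bg"
        p.write_text("chrX\t0\t10\t1\n")
        with pytest.raises(FormatError, match="chrX"):
            read_bedgraph(p, {"chr1": 20})
        p.write_text("chr1\t0\t30\t1\n")
        with pytest.raises(FormatError, match="beyond"):
            read_bedgraph(p, {"chr1": 20})

    def test_random_file_matches_naive_fill(self, tmp_path, rng):
        length = 5000
        edges = np.sort(rng.choice(np.arange(1, length), size=200, replace=False))
        bounds = np.concatenate(([0], edges, [length]))
        naive = np.zeros(length)
        lines = []
        for s, e in zip(bounds[:-1], bounds[1:]):
            if rng.random() < 0.5:
                continue  # leave a gap
            v = float(np.round(rng.random() * 10, 3))
            naive[s:e] = v
            lines.append(f"chr1\t{s}\t{e}\t{v}\n")
        p = tmp_path / "t.bg"
        p.write_text("".join(lines))
        t = read_bedgraph(p, {"chr1": length})
        np.testing.assert_allclose(t.chrom_values("chr1"), naive, rtol=1e-6)

    def test_write_read_conserves_mass(self, tmp_path, rng):
        arr = np.round(rng.random(1000) * 3, 2).astype(np.float32)
        track = CoverageTrack("t", {"chr1": arr})
        p = tmp_path / "t.bg"
        write_bedgraph(track, p)
        back = read_bedgraph(p, {"chr1": 1000})
        np.testing.assert_allclose(back.chrom_values("chr1"), arr, rtol=1e-4)


class TestDeTable:
    def make(self, tmp_path, drop=None):
        df = pd.DataFrame(
            {"gene_id": ["g1"], "chrom": ["chr1"], "tss": [5000], "strand": ["+"],
             "log2fc": [1.0], "pvalue": [0.001], "fdr": [0.01]}
        )
        if drop:
            df = df.drop(columns=[drop])
        p = tmp_path / "de.tsv"
        df.to_csv(p, sep="\t", index=False)
        return p

    def test_fold_change_derived(self, tmp_path):
        df = read_de_table(self.make(tmp_path))
        assert df.loc[0, "fold_change"] == pytest.approx(2.0)

    def test_missing_column_named(self, tmp_path):
        with pytest.raises(FormatError, match="fdr"):
            read_de_table(self.make(tmp_path, drop="fdr"))

    def test_non_numeric_statistic_row_named(self, tmp_path):
        p = self.make(tmp_path)
        text = p.read_text().replace("0.001", "abc")
        p.write_text(text)
        with pytest.raises(FormatError, match="row 1"):
            read_de_table(p)

    def test_order_and_count_preserved(self, tmp_path, rng):
        n = 100
        df = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in rng.permutation(n)], "chrom": "chr1",
             "tss": rng.integers(0, 10_000, n), "strand": ".",
             "log2fc": rng.normal(size=n), "pvalue": rng.uniform(0.001, 1, n),
             "fdr": rng.uniform(0.001, 1, n)}
        )
        p = tmp_path / "de.tsv"
        write_de_table(df, p)
        back = read_de_table(p)
        assert list(back["gene_id"]) == list(df["gene_id"])
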