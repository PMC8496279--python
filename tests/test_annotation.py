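"""Tests for SI extraction, WGA intersection and site filtering."""

import numpy as np
import pytest

from sispec.annotation import (
    SiteRecord,
    apply_site_filters,
    extract_short_introns,
    intersect_homologous_sites,
    read_bed,
    reverse_complement,
)


def write_toy_genome(tmp_path, name, genes, length=1200, seed=0):
    """A single-chromosome genome with two-exon genes.

    ``genes`` is a list of (exon1_start, exon1_end, exon2_start, exon2_end,
    strand) in 0-based half-open coordinates; the gap is the intron.
    """
    rng = np.random.default_rng(seed)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
    fasta = tmp_path / f"{name}.fa"
    fasta.write_text(">chr1\n" + seq + "\n")
    gff = tmp_path / f"{name}.gff3"
    lines = ["##gff-version 3"]
    for g, (e1s, e1e, e2s, e2e, strand) in enumerate(genes):
        gid = f"g{g}"
        lines += [
            f"chr1\ttoy\tgene\t{e1s + 1}\t{e2e}\t.\t{strand}\t.\tID={gid}",
            f"chr1\ttoy\tmRNA\t{e1s + 1}\t{e2e}\t.\t{strand}\t.\tID={gid}.t;Parent={gid}",
            f"chr1\ttoy\texon\t{e1s + 1}\t{e1e}\t.\t{strand}\t.\tID={gid}.e1;Parent={gid}.t",
            f"chr1\ttoy\texon\t{e2s + 1}\t{e2e}\t.\t{strand}\t.\tID={gid}.e2;Parent={gid}.t",
        ]
    gff.write_text("\n".join(lines) + "\n")
    return gff, fasta, seq


class TestExtract:
    def test_length_65_plus_strand_gives_23_sites(self, tmp_path):
        # intron occupies [130, 195): length 65, SI region positions 8..30
        gff, fasta, seq = write_toy_genome(
            tmp_path, "a", [(100, 130, 195, 225, "+")]
        )
        recs = extract_short_introns(gff, fasta, "A")
        assert len(recs) == 1
        r = recs[0]
        assert (r.si_start["A"], r.si_end["A"]) == (137, 160)
        assert r.si_end["A"] - r.si_start["A"] == 23
        assert r.sequence["A"] == seq[130:195]
        assert r.gc_species["A"] == pytest.approx(
            sum(c in "GC" for c in seq[137:160]) / 23
        )

    def test_length_66_excluded(self, tmp_path):
        gff, fasta, _ = write_toy_genome(tmp_path, "b", [(100, 130, 196, 226, "+")])
        assert extract_short_introns(gff, fasta, "A") == []

    def test_si_region_overlapping_exon_excluded(self, tmp_path):
        # second gene's exon lands inside the first gene's SI region
        gff, fasta, _ = write_toy_genome(
            tmp_path, "c",
            [(100, 130, 195, 225, "+"), (140, 150, 400, 430, "+")],
        )
        recs = extract_short_introns(gff, fasta, "A")
        assert all(r.start["A"] != 130 for r in recs)

    def test_overlap_with_long_intron_excluded(self, tmp_path):
        # a >65 bp intron of another transcript covering the SI region
        gff, fasta, _ = write_toy_genome(
            tmp_path, "d",
            [(100, 130, 195, 225, "+"), (60, 90, 300, 330, "+")],
        )
        recs = extract_short_introns(gff, fasta, "A")
        assert recs == []

    @pytest.mark.parametrize("length", [30, 40, 65])
    def test_minus_strand_si_is_reverse_complement(self, tmp_path, length):
        start, end = 130, 130 + length
        gff, fasta, seq = write_toy_genome(
            tmp_path, f"m{length}", [(100, start, end, end + 30, "-")]
        )
        recs = extract_short_introns(gff, fasta, "A")
        assert len(recs) == 1
        r = recs[0]
        # 5' end of a minus-strand intron is its genomic right edge
        si_s, si_e = r.si_start["A"], r.si_end["A"]
        assert (si_s, si_e) == (end - 30, end - 7)
        assert r.sequence["A"] == reverse_complement(seq[start:end])

    def test_intron_shorter_than_30_excluded(self, tmp_path):
        gff, fasta, _ = write_toy_genome(tmp_path, "s", [(100, 130, 155, 185, "+")])
        assert extract_short_introns(gff, fasta, "A") == []

    def test_duplicate_transcript_introns_collapsed(self, tmp_path):
        gff, fasta, _ = write_toy_genome(
            tmp_path, "dup",
            [(100, 130, 195, 225, "+"), (100, 130, 195, 225, "+")],
        )
        recs = extract_short_introns(gff, fasta, "A")
        assert len(recs) == 1


class TestIntersect:
    def _two_species(self, tmp_path):
        gff_a, fa_a, seq_a = write_toy_genome(tmp_path, "spA",
                                              [(100, 130, 195, 225, "+")], seed=1)
        gff_b, fa_b, seq_b = write_toy_genome(tmp_path, "spB",
                                              [(100, 130, 195, 225, "+")], seed=2)
        si_a = extract_short_introns(gff_a, fa_a, "A")
        si_b = extract_short_introns(gff_b, fa_b, "B")
        return si_a, si_b, seq_a, seq_b

    def _wga_line(self, pos_a, pos_b, aa, ab, ao):
        return (f"chr1\t{pos_a}\t{pos_a + 1}\t+\t{aa}\t"
                f"chr1\t{pos_b}\t{pos_b + 1}\t+\t{ab}\t{ao}\n")

    def test_column_in_both_si_regions_kept(self, tmp_path):
        si_a, si_b, seq_a, seq_b = self._two_species(tmp_path)
        wga = tmp_path / "w.bed"
        wga.write_text(self._wga_line(140, 140, seq_a[140], seq_b[140], "G"))
        sites = intersect_homologous_sites(si_a, si_b, wga, "A", "B")
        assert len(sites) == 1
        assert sites[0].pos == {"A": 140, "B": 140}
        assert sites[0].intron_id_b == si_b[0].intron_id

    def test_column_si_in_one_species_dropped(self, tmp_path):
        si_a, si_b, seq_a, seq_b = self._two_species(tmp_path)
        wga = tmp_path / "w.bed"
        # position 500 is outside every SI region of species B
        wga.write_text(self._wga_line(140, 500, seq_a[140], "A", "G"))
        assert intersect_homologous_sites(si_a, si_b, wga, "A", "B") == []

    def test_column_with_outgroup_gap_dropped(self, tmp_path):
        si_a, si_b, seq_a, seq_b = self._two_species(tmp_path)
        wga = tmp_path / "w.bed"
        wga.write_text(
            self._wga_line(140, 140, seq_a[140], seq_b[140], "-")
            + self._wga_line(141, 141, seq_a[141], seq_b[141], "N")
        )
        assert intersect_homologous_sites(si_a, si_b, wga, "A", "B") == []


def _clean_site(**kw):
    base = dict(
        intron_id="i0",
        chrom={"A": "chr1", "B": "chr1"},
        pos={"A": 10, "B": 20},
        ref_allele={"A": "A", "B": "A"},
        outgroup_allele="A",
        ingroup_column="AAAAA",
    )
    base.update(kw)
    return SiteRecord(**base)


class TestFilters:
    def test_qual_below_threshold_removed(self):
        sites = [_clean_site(qual=29.0), _clean_site(qual=30.0), _clean_site()]
        kept = apply_site_filters(sites, qual_threshold=30.0)
        assert len(kept) == 2  # invariant site (qual None) passes by default

    def test_masked_and_flagged_sites_removed(self):
        sites = [
            _clean_site(masked=True),
            _clean_site(indel_overlap=True),
            _clean_site(crossover_region=False),
            _clean_site(autosomal=False),
            _clean_site(),
        ]
        kept = apply_site_filters(sites)
        assert len(kept) == 1

    def test_exclusion_bed_removed(self, tmp_path):
        bed = tmp_path / "x.bed"
        bed.write_text("chr1\t5\t15\n")
        sites = [_clean_site(), _clean_site(pos={"A": 100, "B": 100})]
        kept = apply_site_filters(sites, {"A": read_bed(bed)})
        assert len(kept) == 1
        assert kept[0].pos["A"] == 100

    def test_polymorphism_mode_drops_missing(self):
        sites = [_clean_site(ingroup_column="AANAA"), _clean_site()]
        assert len(apply_site_filters(sites, polymorphism_mode=True)) == 1
        assert len(apply_site_filters(sites, polymorphism_mode=False)) == 2

    def test_idempotent(self):
        sites = [_clean_site(qual=29.0), _clean_site(), _clean_site(masked=True)]
        once = apply_site_filters(sites)
        twice = apply_site_filters(once)
        assert once == twice
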