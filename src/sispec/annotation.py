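"""Short-intron (SI) site extraction, homologous intersection and filtering.

SI sites are the 8-30 bp region (1-based, inclusive, counted from the 5'
end, strand-aware) of introns no longer than 65 bp.  A candidate region is
discarded if it overlaps an exon, an intron longer than 65 bp, or the
non-8-30 bp portion of another short intron — these neighbouring features
are under splicing-related constraint and would contaminate the putatively
neutral set.

Homologous SI sites across two species are taken from whole-genome-alignment
columns (a WGA-BED-style TSV); a column is kept only if it is an SI site in
*both* species and all three reference alleles (two ingroups + outgroup) are
unambiguous bases.

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive) is
converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
from intervaltree import IntervalTree
from pyfaidx import Fasta

__all__ = [
    "IntronRecord",
    "SiteRecord",
    "extract_short_introns",
    "intersect_homologous_sites",
    "apply_site_filters",
    "attach_polymorphism",
    "read_bed",
]

log = logging.getLogger(__name__)

MAX_INTRON_LEN = 65
SI_FIRST = 8  # 1-based inclusive position from the intron's 5' end
SI_LAST = 30

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class IntronRecord:
    """A short intron with its SI sub-region, possibly in several species.

    Per-species values are keyed by species name; a single-species record
    (as produced by :func:`extract_short_introns`) has one key.
    """

    intron_id: str
    chrom: dict[str, str]
    start: dict[str, int]  # full intron, 0-based half-open
    end: dict[str, int]
    strand: dict[str, str]
    sequence: dict[str, str]  # full intron sequence, 5'->3'
    si_start: dict[str, int]  # SI region, genomic 0-based half-open
    si_end: dict[str, int]
    gc_species: dict[str, float] = field(default_factory=dict)

    @property
    def gc_mean(self) -> float:
        vals = list(self.gc_species.values())
        return float(np.mean(vals))

    def species(self) -> list[str]:
        return list(self.chrom)


@dataclass
class SiteRecord:
    """One homologous SI site (an alignment column)."""

    intron_id: str
    chrom: dict[str, str]
    pos: dict[str, int]  # 0-based
    ref_allele: dict[str, str]  # the two ingroup reference alleles
    outgroup_allele: str
    ingroup_column: str = ""  # n haploid calls in the focal species, may hold N
    qual: float | None = None  # None for invariant sites
    masked: bool = False
    indel_overlap: bool = False
    crossover_region: bool = True  # lies in a crossover (i.e. analyzable) region
    autosomal: bool = True
    intron_id_b: str = ""  # homologous intron in the second species


def _si_interval(start: int, end: int, strand: str) -> tuple[int, int]:
    """Genomic 0-based half-open coordinates of intron positions 8..30."""
    if strand == "-":
        return end - SI_LAST, end - (SI_FIRST - 1)
    return start + (SI_FIRST - 1), start + SI_LAST


def _gc(seq: str) -> float:
    seq = seq.upper()
    denom = sum(seq.count(b) for b in "ACGT")
    if denom == 0:
        raise ValueError("all-N sequence: GC undefined")
    return (seq.count("G") + seq.count("C")) / denom


def _introns_from_db(db) -> list[tuple[str, int, int, str]]:
    """(chrom, start0, end0, strand) of every intron, explicit or exon-gap."""
    found = set()
    if any(True for _ in db.features_of_type("intron", limit=None)):
        for f in db.features_of_type("intron"):
            found.add((f.seqid, f.start - 1, f.end, f.strand))
        return sorted(found)
    # reconstruct from exon gaps within each transcript
    parents = set()
    for exon in db.features_of_type("exon"):
        for p in db.parents(exon, level=1):
            parents.add(p.id)
    for pid in sorted(parents):
        exons = sorted(
            db.children(pid, featuretype="exon"), key=lambda f: f.start
        )
        for a, b in zip(exons, exons[1:]):
            if b.start > a.end + 1:
                found.add((a.seqid, a.end, b.start - 1, a.strand))
    return sorted(found)


def extract_short_introns(
    gff_path: str | Path,
    fasta_path: str | Path,
    species: str,
    max_len: int = MAX_INTRON_LEN,
) -> list[IntronRecord]:
    """Extract SI regions of introns of length <= ``max_len`` for one species.

    A candidate is excluded if its SI region overlaps an exon, a long intron,
    or the non-SI portion of another short intron (duplicate intron
    coordinates from alternative transcripts are collapsed first).
    """
    try:
        db = gffutils.create_db(
            str(gff_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # pragma: no cover - gffutils reports the line
        raise ValueError(f"malformed GFF3 {gff_path}: {exc}") from exc
    genome = Fasta(str(fasta_path), sequence_always_upper=True)

    introns = _introns_from_db(db)
    exclusion = {}

    def tree(chrom) -> IntervalTree:
        if chrom not in exclusion:
            exclusion[chrom] = IntervalTree()
        return exclusion[chrom]

    for f in db.features_of_type("exon"):
        tree(f.seqid).addi(f.start - 1, f.end)

    short, seen = [], set()
    for chrom, s, e, strand in introns:
        key = (chrom, s, e)
        if key in seen:
            continue  # one copy per genomic interval (alternative transcripts)
        seen.add(key)
        length = e - s
        if length > max_len:
            tree(chrom).addi(s, e)  # long introns are exclusion zones
            continue
        if length < SI_LAST:
            # too short to carry the full 8-30 bp region
            continue
        short.append((chrom, s, e, strand))
        si_s, si_e = _si_interval(s, e, strand)
        if si_s > s:
            tree(chrom).addi(s, si_s)  # non-SI 5' portion
        if si_e < e:
            tree(chrom).addi(si_e, e)  # non-SI 3' portion

    records = []
    for i, (chrom, s, e, strand) in enumerate(short):
        si_s, si_e = _si_interval(s, e, strand)
        hits = tree(chrom).overlap(si_s, si_e)
        # ignore this intron's own non-SI flanks
        own = {(s, si_s), (si_e, e)}
        if any((h.begin, h.end) not in own for h in hits):
            continue
        if chrom not in genome:
            raise ValueError(f"chromosome {chrom!r} absent from {fasta_path}")
        if e > len(genome[chrom]):
            raise ValueError(
                f"intron {chrom}:{s}-{e} extends past the end of the sequence"
            )
        full = str(genome[chrom][s:e])
        si_seq = str(genome[chrom][si_s:si_e])
        if strand == "-":
            full = reverse_complement(full)
            si_seq = reverse_complement(si_seq)
        rec = IntronRecord(
            intron_id=f"{species}:{chrom}:{s}-{e}:{strand}",
            chrom={species: chrom},
            start={species: s},
            end={species: e},
            strand={species: strand},
            sequence={species: full},
            si_start={species: si_s},
            si_end={species: si_e},
        )
        try:
            rec.gc_species[species] = _gc(si_seq)
        except ValueError:
            continue  # all-N SI region carries no information
        records.append(rec)
    log.info("%s: %d short introns with clean SI regions", species, len(records))
    return records


def _si_trees(records: list[IntronRecord], species: str) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in records:
        t = trees.setdefault(r.chrom[species], IntervalTree())
        t.addi(r.si_start[species], r.si_end[species], r)
    return trees


def intersect_homologous_sites(
    si_a: list[IntronRecord],
    si_b: list[IntronRecord],
    wga_path: str | Path,
    species_a: str = "A",
    species_b: str = "B",
) -> list[SiteRecord]:
    """Join WGA columns to the SI annotations of both species.

    The WGA-BED file is a TSV with columns
    ``chrom_a start_a end_a strand_a allele_a chrom_b start_b end_b strand_b
    allele_b allele_out`` (0-based half-open, one alignment column per row).
    A column is kept when it lies in an SI region of both species and all
    three reference alleles are A/C/G/T.
    """
    trees_a = _si_trees(si_a, species_a)
    trees_b = _si_trees(si_b, species_b)
    sites: list[SiteRecord] = []
    skipped = {"missing_species": 0, "not_si_both": 0, "ambiguous_allele": 0}
    with open(wga_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 11:
                skipped["missing_species"] += 1
                continue
            ca, sa, _, stra, aa, cb, sb, _, strb, ab, ao = parts[:11]
            sa, sb = int(sa), int(sb)
            hits_a = trees_a.get(ca, IntervalTree()).at(sa)
            hits_b = trees_b.get(cb, IntervalTree()).at(sb)
            if not hits_a or not hits_b:
                skipped["not_si_both"] += 1
                continue
            if any(x.upper() not in "ACGT" for x in (aa, ab, ao)):
                skipped["ambiguous_allele"] += 1
                continue
            intron = next(iter(hits_a)).data
            intron_b = next(iter(hits_b)).data
            sites.append(
                SiteRecord(
                    intron_id=intron.intron_id,
                    intron_id_b=intron_b.intron_id,
                    chrom={species_a: ca, species_b: cb},
                    pos={species_a: sa, species_b: sb},
                    ref_allele={species_a: aa.upper(), species_b: ab.upper()},
                    outgroup_allele=ao.upper(),
                )
            )
    log.info("WGA intersection: kept %d columns, skipped %s", len(sites), skipped)
    return sites


def read_bed(path: str | Path) -> dict[str, IntervalTree]:
    """BED intervals (0-based half-open) as per-chromosome interval trees."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.split("\t")[:3]
            trees.setdefault(chrom, IntervalTree()).addi(int(start), int(end))
    return trees


def apply_site_filters(
    sites: list[SiteRecord],
    exclusions: dict[str, dict[str, IntervalTree]] | None = None,
    qual_threshold: float = 30.0,
    polymorphism_mode: bool = False,
) -> list[SiteRecord]:
    """Retain sites passing the study's filters.

    A site survives if it is autosomal in both species, unmasked in all
    references, free of indel overlap, QUAL-passing (invariant sites, with
    ``qual is None``, pass by default) and outside the excluded
    (non-crossover / repeat) regions of every species.  In polymorphism mode
    sites with any missing ingroup allele are dropped as well.

    ``exclusions`` maps species name -> per-chromosome interval trees.
    """
    removed = {
        "autosomal": 0,
        "masked": 0,
        "indel": 0,
        "qual": 0,
        "noncrossover": 0,
        "excluded_bed": 0,
        "missing_polymorphism": 0,
    }
    kept = []
    for s in sites:
        if not s.autosomal:
            removed["autosomal"] += 1
            continue
        if s.masked:
            removed["masked"] += 1
            continue
        if s.indel_overlap:
            removed["indel"] += 1
            continue
        if s.qual is not None and s.qual < qual_threshold:
            removed["qual"] += 1
            continue
        if not s.crossover_region:
            removed["noncrossover"] += 1
            continue
        if exclusions:
            hit = False
            for sp, trees in exclusions.items():
                if sp in s.pos and trees.get(s.chrom[sp], IntervalTree()).at(s.pos[sp]):
                    hit = True
                    break
            if hit:
                removed["excluded_bed"] += 1
                continue
        if polymorphism_mode and (
            not s.ingroup_column or any(c not in "ACGT" for c in s.ingroup_column)
        ):
            removed["missing_polymorphism"] += 1
            continue
        kept.append(s)
    log.info("site filters: kept %d of %d; removed %s", len(kept), len(sites), removed)
    return kept


def attach_polymorphism(
    sites: list[SiteRecord], haplotype_fasta: str | Path, species: str
) -> list[SiteRecord]:
    """Fill each site's ingroup column from a multi-FASTA of haplotypes
    aligned to the focal species' reference coordinates."""
    haps = Fasta(str(haplotype_fasta), sequence_always_upper=True)
    # haplotype genomes are modest; hold them in memory for column slicing
    seqs = {name: str(haps[name][:]) for name in haps.keys()}
    for s in sites:
        pos = s.pos[species]
        s.ingroup_column = "".join(seq[pos] for seq in seqs.values())
    return sites
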