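"""Marker maps, annotations, allele-count tables and region IO.

All in-memory coordinates are 1-based inclusive, matching the genetics
convention ("chrVIII 51111-52988").  BED output is 0-based half-open per
the standard; the conversion is done only at the file boundary.

A :class:`MarkerMap` is the biallelic SNP scaffold of a two-parent cross.
Each marker carries a position in *both* parental reference coordinate
systems (the two strains of the cross differ by small indels, so the same
physical site has slightly different coordinates in each assembly).  The
correspondence is carried per-marker rather than via a liftover chain:
the analysis only ever needs marker-level correspondence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger("ebsa")

REF_A = "refA"
REF_B = "refB"
REFERENCES = (REF_A, REF_B)

#: canonical column order of the marker table
MARKER_COLUMNS = ["chrom_a", "pos_a", "chrom_b", "pos_b", "allele_a", "allele_b"]
COUNT_COLUMNS = ["marker", "pool", "n_a", "n_b", "reference"]

_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """Raised when an input file violates the declared dialect."""


# ---------------------------------------------------------------------------
# MarkerMap
# ---------------------------------------------------------------------------


@dataclass
class MarkerMap:
    """Ordered biallelic SNP markers with coordinates in both references.

    Parameters
    ----------
    df
        One row per marker with columns ``chrom_a, pos_a, chrom_b, pos_b,
        allele_a, allele_b``.  ``allele_a`` is the base carried by the
        parent-A reference at that site, ``allele_b`` the parent-B base.
    genome_lengths
        ``{"refA": {chrom: bp}, "refB": {chrom: bp}}``.  Optional; needed
        by the simulator to place crossovers on physical chromosomes.
    """

    df: pd.DataFrame
    genome_lengths: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in MARKER_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"marker table missing columns: {missing}")
        self.df = self.df[MARKER_COLUMNS].reset_index(drop=True)
        self.df["pos_a"] = self.df["pos_a"].astype(np.int64)
        self.df["pos_b"] = self.df["pos_b"].astype(np.int64)
        self._validate()

    def _validate(self) -> None:
        df = self.df
        same = df["allele_a"].to_numpy() == df["allele_b"].to_numpy()
        if same.any():
            i = int(np.flatnonzero(same)[0])
            raise FormatError(
                f"marker {i} ({df.chrom_a[i]}:{df.pos_a[i]}) has identical "
                f"alleles {df.allele_a[i]!r}"
            )
        for chrom_col, pos_col, ref in (
            ("chrom_a", "pos_a", REF_A),
            ("chrom_b", "pos_b", REF_B),
        ):
            if df.duplicated([chrom_col, pos_col]).any():
                raise FormatError(f"duplicate positions in {ref}")
            if not self._is_sorted(df, chrom_col, pos_col):
                logger.warning("marker table not sorted by %s; sorting", ref)
                self.df = df = df.sort_values(
                    [chrom_col, pos_col], kind="stable"
                ).reset_index(drop=True)
        # bijection refA<->refB: duplicates checked above, so position pairs
        # are a bijection iff both columns are duplicate-free (they are).

    @staticmethod
    def _is_sorted(df: pd.DataFrame, chrom_col: str, pos_col: str) -> bool:
        grp = df.groupby(chrom_col, sort=False)[pos_col]
        return bool(grp.apply(lambda s: s.is_monotonic_increasing).all())

    def __len__(self) -> int:
        return len(self.df)

    def chroms(self, reference: str = REF_A) -> list[str]:
        col = "chrom_a" if reference == REF_A else "chrom_b"
        return list(dict.fromkeys(self.df[col]))

    def positions(self, reference: str = REF_A) -> np.ndarray:
        return self.df["pos_a" if reference == REF_A else "pos_b"].to_numpy()

    def chrom_markers(self, chrom: str, reference: str = REF_A) -> np.ndarray:
        """Indices of markers on ``chrom`` in map order."""
        col = "chrom_a" if reference == REF_A else "chrom_b"
        return np.flatnonzero((self.df[col] == chrom).to_numpy())

    def chrom_length(self, chrom: str, reference: str = REF_A) -> int:
        lengths = self.genome_lengths.get(reference, {})
        if chrom in lengths:
            return int(lengths[chrom])
        # fall back to the last marker position
        idx = self.chrom_markers(chrom, reference)
        if idx.size == 0:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return int(self.positions(reference)[idx].max())

    def equals(self, other: "MarkerMap") -> bool:
        return self.df.equals(other.df)


# ---------------------------------------------------------------------------
# AnnotationSet
# ---------------------------------------------------------------------------


@dataclass
class AnnotationSet:
    """Gene and intergenic-interval annotations (refA coordinates).

    ``genes`` columns: ``gene, chrom, start, end, strand, tss``.
    ``intergenic`` columns: ``region, chrom, start, end, left_gene,
    right_gene``.  ``cds`` maps gene id to its coding sequence (parent-A
    reference orientation of the genome, i.e. the + strand slice; the
    strand column says whether to reverse-complement before translating).
    """

    genes: pd.DataFrame
    intergenic: pd.DataFrame = field(default_factory=pd.DataFrame)
    cds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.genes
        if len(g):
            if (g["end"] < g["start"]).any():
                raise FormatError("gene interval with negative length")
            plus = g["strand"] == "+"
            tss_ok = np.where(plus, g["tss"] == g["start"], g["tss"] == g["end"])
            bad = ~tss_ok & g["tss"].notna().to_numpy()
            if bad.any():
                raise FormatError("TSS inconsistent with strand")
        if len(self.intergenic) and (
            self.intergenic["end"] < self.intergenic["start"]
        ).any():
            raise FormatError("intergenic interval with negative length")


# ---------------------------------------------------------------------------
# AlleleCountTable
# ---------------------------------------------------------------------------


@dataclass
class AlleleCountTable:
    """Per-marker, per-pool pooled-sequencing read counts.

    ``df`` columns: ``marker`` (index into a MarkerMap), ``pool`` (label),
    ``n_a``/``n_b`` (reads supporting the parent-A / parent-B allele) and
    ``reference`` (the genome the pool's reads were mapped against, which
    matters because reference-mapping bias drops non-reference reads).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COUNT_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"count table missing columns: {missing}")
        self.df = self.df[COUNT_COLUMNS].reset_index(drop=True)
        if (self.df[["n_a", "n_b"]] < 0).to_numpy().any():
            raise FormatError("negative read counts")
        bad_ref = ~self.df["reference"].isin(REFERENCES)
        if bad_ref.any():
            raise FormatError(
                f"unknown reference label {self.df['reference'][bad_ref].iloc[0]!r}"
            )
        if self.df.duplicated(["marker", "pool", "reference"]).any():
            raise FormatError("duplicate (marker, pool, reference) rows")

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# marker table IO
# ---------------------------------------------------------------------------


def read_marker_table(path: str | Path, dialect: str = "tsv") -> MarkerMap:
    """Read a marker map from a 6-column TSV or a biallelic-SNP VCF.

    The TSV dialect has the columns of :data:`MARKER_COLUMNS` (header row
    required).  The VCF dialect takes CHROM/POS/REF/ALT as the parent-A
    coordinates and alleles; the parent-B position is read from the
    ``CB``/``PB`` INFO keys when present, else mirrored from parent A.
    Multi-allelic or non-SNP records are a format error.
    """
    path = Path(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#")
        return MarkerMap(df)
    if dialect == "vcf":
        rows = []
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                if rec.alts is None or len(rec.alts) != 1:
                    raise FormatError(
                        f"non-biallelic record at {rec.chrom}:{rec.pos}"
                    )
                ref, alt = rec.ref, rec.alts[0]
                if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                    raise FormatError(f"non-SNP record at {rec.chrom}:{rec.pos}")
                chrom_b = rec.info.get("CB", rec.chrom)
                pos_b = int(rec.info.get("PB", rec.pos))
                rows.append((rec.chrom, rec.pos, chrom_b, pos_b, ref, alt))
        df = pd.DataFrame(rows, columns=MARKER_COLUMNS)
        return MarkerMap(df)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_marker_table(
    marker_map: MarkerMap, path: str | Path, dialect: str = "tsv"
) -> Path:
    """Write a marker map as TSV or VCF (parent-B coordinates in INFO)."""
    path = Path(path)
    if dialect == "tsv":
        marker_map.df.to_csv(path, sep="\t", index=False)
        return path
    if dialect == "vcf":
        header = pysam.VariantHeader()
        header.add_line('##INFO=<ID=CB,Number=1,Type=String,Description="Chromosome in parent-B reference">')
        header.add_line('##INFO=<ID=PB,Number=1,Type=Integer,Description="1-based position in parent-B reference">')
        lengths = marker_map.genome_lengths.get(REF_A, {})
        for chrom in marker_map.chroms(REF_A):
            length = lengths.get(chrom)
            if length:
                header.contigs.add(chrom, length=int(length))
            else:
                header.contigs.add(chrom)
        with pysam.VariantFile(str(path), "w", header=header) as out:
            for row in marker_map.df.itertuples(index=False):
                rec = out.new_record(
                    contig=row.chrom_a,
                    start=row.pos_a - 1,
                    stop=row.pos_a,
                    alleles=(row.allele_a, row.allele_b),
                )
                rec.info["CB"] = row.chrom_b
                rec.info["PB"] = int(row.pos_b)
                out.write(rec)
        return path
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# count table IO
# ---------------------------------------------------------------------------


def read_counts_tsv(path: str | Path) -> AlleleCountTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    return AlleleCountTable(df)


def write_counts_tsv(counts: AlleleCountTable, path: str | Path) -> Path:
    path = Path(path)
    counts.df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# regions BED IO
# ---------------------------------------------------------------------------

_BED_HEADER = "# candidate regions (BED6: chrom, start0, end, name, n_snps, strand)"


def write_regions_bed(regions: Iterable, path: str | Path) -> Path:
    """Write candidate regions as BED6.

    Internal coordinates are 1-based inclusive, so a region start ``s``
    becomes BED start ``s - 1`` and the end is emitted unchanged.  The
    score column carries the number of concordant SNPs.  Overlapping
    regions on one chromosome are rejected.
    """
    regions = list(regions)
    by_chrom: dict[str, list] = {}
    for r in regions:
        if r.end < r.start:
            raise ValueError(f"region {r.chrom}:{r.start}-{r.end} has end < start")
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, rs in by_chrom.items():
        rs.sort(key=lambda r: r.start)
        for prev, nxt in zip(rs, rs[1:]):
            if nxt.start <= prev.end:
                raise ValueError(
                    f"overlapping regions on {chrom}: "
                    f"{prev.start}-{prev.end} and {nxt.start}-{nxt.end}"
                )
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_BED_HEADER + "\n")
        i = 0
        for chrom in by_chrom:
            for r in by_chrom[chrom]:
                i += 1
                name = getattr(r, "name", None) or f"region_{i}"
                fh.write(
                    f"{chrom}\t{r.start - 1}\t{r.end}\t{name}\t{r.n_markers}\t.\n"
                )
    return path


def read_regions_bed(path: str | Path):
    """Read BED6 regions back into :class:`~ebsa.af_scan.CandidateRegion`."""
    from .af_scan import CandidateRegion  # local import avoids a cycle

    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start0, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else None
            n_markers = int(fields[4]) if len(fields) > 4 else 0
            regions.append(
                CandidateRegion(
                    chrom=chrom, start=start0 + 1, end=end,
                    n_markers=n_markers, name=name,
                )
            )
    return regions


# ---------------------------------------------------------------------------
# GFF3 annotations
# ---------------------------------------------------------------------------


def read_annotation_gff(path: str | Path) -> AnnotationSet:
    """Read gene and intergenic_region features from a GFF3 file.

    Feature types used: ``gene`` (TSS inferred from strand) and
    ``intergenic_region`` (flanking gene ids in ``left_gene``/``right_gene``
    attributes when present).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    gene_rows, ig_rows = [], []
    for feat in db.all_features():
        fid = feat.attributes.get("ID", [feat.id])[0]
        if feat.featuretype == "gene":
            tss = feat.start if feat.strand == "+" else feat.end
            gene_rows.append(
                (fid, feat.seqid, feat.start, feat.end, feat.strand, tss)
            )
        elif feat.featuretype == "intergenic_region":
            left = feat.attributes.get("left_gene", [""])[0]
            right = feat.attributes.get("right_gene", [""])[0]
            ig_rows.append((fid, feat.seqid, feat.start, feat.end, left, right))
    genes = pd.DataFrame(
        gene_rows, columns=["gene", "chrom", "start", "end", "strand", "tss"]
    )
    intergenic = pd.DataFrame(
        ig_rows, columns=["region", "chrom", "start", "end", "left_gene", "right_gene"]
    )
    return AnnotationSet(genes=genes, intergenic=intergenic)


def write_annotation_gff(annotations: AnnotationSet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in annotations.genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\tebsa\tgene\t{row.start}\t{row.end}\t.\t{row.strand}\t."
                f"\tID={row.gene}\n"
            )
        for row in annotations.intergenic.itertuples(index=False):
            fh.write(
                f"{row.chrom}\tebsa\tintergenic_region\t{row.start}\t{row.end}\t.\t.\t."
                f"\tID={row.region};left_gene={row.left_gene};right_gene={row.right_gene}\n"
            )
    return path
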