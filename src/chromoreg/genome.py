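"""Gene models, adjacency and transcriptional orientation.

Genes are flat stranded intervals ordered along chromosomes.  All internal
coordinates are 0-based half-open; GFF3 (1-based inclusive) and BED
(0-based half-open) are converted at the I/O boundary.

Adjacent gene pairs are classified by the strand combination of the
left/right gene (left = smaller coordinate):

* ``FF`` — tandem forward (+,+)
* ``RR`` — tandem reverse (-,-)
* ``RF`` — outward/divergent (-,+): both 5' regulatory regions face the
  single intergenic interval between the genes, so the pair shares a
  promoter-containing intergenic region
* ``FR`` — convergent (+,-)

RF is the only orientation in which a single regulatory element between
the genes can drive both, which is why it is singled out throughout the
pair-association analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import gffutils

from .errors import InputError, ValidationError

logger = logging.getLogger(__name__)

FORWARD = "+"
REVERSE = "-"
STRANDS = (FORWARD, REVERSE)

#: feature types loaded from GFF3; everything else is counted and skipped
GENE_LIKE_TYPES = ("gene", "tRNA_gene", "tRNA")

#: strand combination (left, right) -> orientation label
ORIENTATION_TABLE = {
    (FORWARD, FORWARD): "FF",
    (REVERSE, REVERSE): "RR",
    (REVERSE, FORWARD): "RF",
    (FORWARD, REVERSE): "FR",
}

ORIENTATIONS = ("FF", "RR", "RF", "FR")


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval; ``start >= end`` encodes an empty interval."""

    start: int
    end: int

    @property
    def is_empty(self) -> bool:
        return self.end <= self.start

    def __len__(self) -> int:
        return max(0, self.end - self.start)


@dataclass(frozen=True)
class Gene:
    """One annotated feature (protein-coding gene or tRNA)."""

    id: str
    chromosome: str
    start: int
    end: int
    strand: str
    feature_type: str = "gene"

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(f"gene {self.id}: invalid strand {self.strand!r}")
        if not self.start < self.end:
            raise ValidationError(
                f"gene {self.id}: invalid interval [{self.start}, {self.end}) "
                "(start must be < end in 0-based half-open coordinates)"
            )

    @property
    def is_trna(self) -> bool:
        return "tRNA" in self.feature_type

    @property
    def interval(self) -> Interval:
        return Interval(self.start, self.end)


@dataclass
class GenomeAnnotation:
    """Per-chromosome ordered gene lists.

    ``chromosomes`` maps chromosome name to a list of :class:`Gene` sorted by
    ``(start, end, id)``; ``sequence_lengths`` is optional bookkeeping used
    when a FASTA is attached.
    """

    chromosomes: dict[str, list[Gene]]
    sequence_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for chrom, genes in self.chromosomes.items():
            self.chromosomes[chrom] = sorted(
                genes, key=lambda g: (g.start, g.end, g.id)
            )
            for g in self.chromosomes[chrom]:
                if g.id in seen:
                    raise ValidationError(
                        f"duplicate gene id {g.id} (on {seen[g.id]} and {chrom})"
                    )
                seen[g.id] = chrom

    def genes(self) -> Iterator[Gene]:
        for genes in self.chromosomes.values():
            yield from genes

    @property
    def n_genes(self) -> int:
        return sum(len(g) for g in self.chromosomes.values())

    def gene_index(self) -> dict[str, Gene]:
        return {g.id: g for g in self.genes()}


@dataclass(frozen=True)
class PairRecord:
    """Two genes adjacent on the same chromosome, with orientation class."""

    left: Gene
    right: Gene
    orientation: str
    intergenic: Interval
    shares_intergenic_promoter_region: bool = field(default=False)

    @staticmethod
    def from_genes(left: Gene, right: Gene) -> "PairRecord":
        orientation = classify_orientation(left.strand, right.strand)
        return PairRecord(
            left=left,
            right=right,
            orientation=orientation,
            intergenic=intergenic_interval(left, right),
            shares_intergenic_promoter_region=orientation == "RF",
        )


def classify_orientation(left_strand: str, right_strand: str) -> str:
    """Orientation label for an adjacent pair, from the two strands alone."""
    try:
        return ORIENTATION_TABLE[(left_strand, right_strand)]
    except KeyError:
        raise ValidationError(
            f"invalid strand combination ({left_strand!r}, {right_strand!r})"
        ) from None


def intergenic_interval(left: Gene, right: Gene) -> Interval:
    """Half-open interval between two adjacent genes; empty when they overlap."""
    return Interval(left.end, right.start)


def adjacent_pairs(annotation: GenomeAnnotation) -> list[PairRecord]:
    """All adjacent gene pairs, chromosome by chromosome (n-1 per chromosome)."""
    pairs: list[PairRecord] = []
    for genes in annotation.chromosomes.values():
        for left, right in zip(genes, genes[1:]):
            pairs.append(PairRecord.from_genes(left, right))
    return pairs


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_gff3(
    path: str,
    feature_types: Sequence[str] = GENE_LIKE_TYPES,
) -> GenomeAnnotation:
    """Load gene-like features from a GFF3 file.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    Features whose type is not in ``feature_types`` are skipped (a summary
    is logged).  Gene ids come from the ``ID=`` attribute.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read GFF3 file {path}: {exc}") from exc

    chromosomes: dict[str, list[Gene]] = {}
    n_skipped = 0
    for feat in db.all_features():
        if feat.featuretype not in feature_types:
            n_skipped += 1
            continue
        if feat.end < feat.start:
            raise ValidationError(
                f"feature {feat.id or '?'} on {feat.seqid}: end < start "
                f"({feat.end} < {feat.start})"
            )
        if feat.strand not in STRANDS:
            raise ValidationError(
                f"feature {feat.id or '?'} on {feat.seqid}: "
                f"missing/invalid strand {feat.strand!r}"
            )
        gene = Gene(
            id=feat.id,
            chromosome=feat.seqid,
            start=feat.start - 1,  # GFF3 -> half-open
            end=feat.end,
            strand=feat.strand,
            feature_type=feat.featuretype,
        )
        chromosomes.setdefault(feat.seqid, []).append(gene)
    if n_skipped:
        logger.info("read_gff3: skipped %d non-gene-like features", n_skipped)
    if not chromosomes:
        raise InputError(f"no gene-like features found in {path}")
    return GenomeAnnotation(chromosomes=chromosomes)


def write_gff3(annotation: GenomeAnnotation, path: str) -> None:
    """Write the annotation back out as minimal GFF3 (inverse of read_gff3)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, genes in annotation.chromosomes.items():
            if annotation.sequence_lengths and chrom in annotation.sequence_lengths:
                fh.write(
                    f"##sequence-region {chrom} 1 "
                    f"{annotation.sequence_lengths[chrom]}\n"
                )
        for chrom, genes in annotation.chromosomes.items():
            for g in genes:
                fh.write(
                    f"{chrom}\tchromoreg\t{g.feature_type}\t{g.start + 1}\t{g.end}"
                    f"\t.\t{g.strand}\t.\tID={g.id}\n"
                )


def write_bed6(genes: Iterable[Gene], path: str) -> None:
    """Export gene loci as BED6 (name=id, score=0)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chromosome}\t{g.start}\t{g.end}\t{g.id}\t0\t{g.strand}\n"
            )
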