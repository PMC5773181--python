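"""Degenerate DNA motif models with bounded spacers, and sequence scanning.

A pattern is an ordered list of allowed-nucleotide sets over {A,C,G,T}
(written as single bases, bracketed classes like ``[GC]``, or ``N`` for
any base) plus at most one bounded spacer ``N{min-max}`` separating two
fixed blocks — the form used for dimeric transcription-factor sites
whose half-sites sit 2-36 bp apart.

The shipped registry holds the carbon-source and iron-responsive yeast
regulator models used throughout the analysis:

* ``mig1_core``   — the Mig1 GC box, ``[GC][TC]GG[GA]G``
* ``mig1_atgc``   — the combined AT box + GC box Mig1 model,
  ``[ATG][AT][AT][AT][ATG]N[GC][TC]GGGG``
* ``adr1_core``   — the Adr1 half-site, ``[TGA][TC]GG[AG]G``
* ``adr1_dimer``  — the dimeric Adr1 model,
  ``C[CT]CC[GA][TCA]N{2-36}[TGA][TC]GG[AG]G`` (its own reverse complement)
* ``aft1_loose``  — Aft1/Aft2 consensus ``[TC]GCACC[TC]``
* ``aft1_strict`` — Aft1/Aft2 consensus PyPuCACCCPu, ``[TC][AG]CACCC[AG]``
* ``aft1_exact``  — the exact consensus ``GTGCACCC``

Scanning reports every matching start position (overlaps allowed); for
spacer patterns, one hit per left anchor using the shortest qualifying
spacer (configurable to all spacer lengths).  An ``N`` in the *sequence*
never matches, including inside a spacer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping, Sequence

from .errors import ConfigError, ValidationError
from .genome import FORWARD, REVERSE, Gene, GenomeAnnotation

BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

_TOKEN_RE = re.compile(
    r"\[(?P<cls>[ACGTacgt]*)\]"        # bracketed class
    r"|N\{(?P<lo>\d+)[-,–](?P<hi>\d+)\}"  # bounded spacer
    r"|(?P<base>[ACGTNacgtn])"         # single base or N
)


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate pattern: per-position base sets + optional spacer.

    ``spacer`` is ``(index, min_gap, max_gap)`` where ``index`` is the
    number of fixed positions preceding the gap.
    """

    name: str
    positions: tuple[frozenset[str], ...]
    spacer: tuple[int, int, int] | None = None
    source: str = ""

    @property
    def n_fixed(self) -> int:
        return len(self.positions)

    @property
    def min_len(self) -> int:
        return self.n_fixed + (self.spacer[1] if self.spacer else 0)

    @property
    def max_len(self) -> int:
        return self.n_fixed + (self.spacer[2] if self.spacer else 0)

    def class_string(self) -> str:
        """Canonical textual form; compile_pattern round-trips it."""
        parts = []
        for i, pos in enumerate(self.positions):
            if self.spacer and i == self.spacer[0]:
                parts.append(f"N{{{self.spacer[1]}-{self.spacer[2]}}}")
            bases = "".join(b for b in BASES if b in pos)
            if len(bases) == 4:
                parts.append("N")
            elif len(bases) == 1:
                parts.append(bases)
            else:
                parts.append(f"[{bases}]")
        if self.spacer and self.spacer[0] == len(self.positions):
            parts.append(f"N{{{self.spacer[1]}-{self.spacer[2]}}}")
        return "".join(parts)

    @property
    def is_self_reverse_complement(self) -> bool:
        return reverse_complement_pattern(self) == replace(self, name=self.name)


@dataclass(frozen=True)
class MotifHit:
    """A located match.  Coordinates are 0-based half-open on the forward
    strand; ``matched_sequence`` is the forward-strand text of the locus
    (reverse-complement it for reverse-strand hits to read the site)."""

    pattern_name: str
    chromosome: str
    start: int
    end: int
    strand: str
    matched_sequence: str
    spacer_length: int | None = None
    context: "HitContext | None" = None


@dataclass(frozen=True)
class HitContext:
    """Relationship of a hit to the annotation.

    ``kind`` is one of ``inside``, ``upstream-of``, ``downstream-of`` or
    ``intergenic`` (the last lists both flanking genes of an RF pair
    whose shared upstream region contains the hit)."""

    kind: str
    gene_ids: tuple[str, ...]
    distance: int


def compile_pattern(
    name: str,
    class_string: str,
    spacer_spec: tuple[int, int] | None = None,
    source: str = "",
) -> MotifPattern:
    """Parse a class string like ``C[CT]CC[GA][TCA]N{2-36}[TGA][TC]GG[AG]G``.

    ``spacer_spec=(min, max)`` may alternatively append a spacer at the
    current end of the pattern (used when concatenating two half-sites).
    """
    positions: list[frozenset[str]] = []
    spacer: tuple[int, int, int] | None = None
    pos = 0
    while pos < len(class_string):
        m = _TOKEN_RE.match(class_string, pos)
        if not m:
            raise ConfigError(
                f"pattern {name!r}: cannot parse {class_string!r} at offset {pos}"
            )
        if m.group("cls") is not None:
            bases = frozenset(m.group("cls").upper())
            if not bases:
                raise ConfigError(
                    f"pattern {name!r}: empty class at offset {pos}"
                )
            positions.append(bases)
        elif m.group("lo") is not None:
            lo, hi = int(m.group("lo")), int(m.group("hi"))
            if spacer is not None:
                raise ConfigError(f"pattern {name!r}: at most one spacer allowed")
            if lo > hi:
                raise ConfigError(
                    f"pattern {name!r}: inverted spacer bounds {lo} > {hi}"
                )
            spacer = (len(positions), lo, hi)
        else:
            base = m.group("base").upper()
            positions.append(frozenset(BASES) if base == "N" else frozenset(base))
        pos = m.end()
    if spacer_spec is not None:
        if spacer is not None:
            raise ConfigError(f"pattern {name!r}: at most one spacer allowed")
        lo, hi = spacer_spec
        if lo > hi:
            raise ConfigError(f"pattern {name!r}: inverted spacer bounds {lo} > {hi}")
        spacer = (len(positions), lo, hi)
    if not positions:
        raise ConfigError(f"pattern {name!r}: no positions parsed")
    return MotifPattern(
        name=name, positions=tuple(positions), spacer=spacer, source=source
    )


def reverse_complement_pattern(pattern: MotifPattern) -> MotifPattern:
    """Reverse the position order, complement each set, mirror the spacer."""
    positions = tuple(
        frozenset(_COMPLEMENT[b] for b in pos)
        for pos in reversed(pattern.positions)
    )
    spacer = None
    if pattern.spacer is not None:
        idx, lo, hi = pattern.spacer
        spacer = (pattern.n_fixed - idx, lo, hi)
    return MotifPattern(
        name=pattern.name, positions=positions, spacer=spacer, source=pattern.source
    )


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

REGISTRY: dict[str, MotifPattern] = {
    p.name: p
    for p in (
        compile_pattern("mig1_core", "[GC][TC]GG[GA]G", source="Mig1 GC box"),
        compile_pattern(
            "mig1_atgc",
            "[ATG][AT][AT][AT][ATG]N[GC][TC]GGGG",
            source="Mig1 combined AT box + GC box",
        ),
        compile_pattern("adr1_core", "[TGA][TC]GG[AG]G", source="Adr1 half-site"),
        compile_pattern(
            "adr1_dimer",
            "C[CT]CC[GA][TCA]N{2-36}[TGA][TC]GG[AG]G",
            source="dimeric Adr1 site (self-reverse-complementary)",
        ),
        compile_pattern("aft1_loose", "[TC]GCACC[TC]", source="Aft1/Aft2 consensus"),
        compile_pattern(
            "aft1_strict", "[TC][AG]CACCC[AG]", source="Aft1/Aft2 PyPuCACCCPu"
        ),
        compile_pattern("aft1_exact", "GTGCACCC", source="Aft1 exact consensus"),
    )
}


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _class_regex(pos: frozenset[str]) -> str:
    bases = "".join(b for b in BASES if b in pos)
    return bases if len(bases) == 1 else f"[{bases}]"


def _pattern_regexes(pattern: MotifPattern) -> re.Pattern:
    if pattern.spacer is None:
        body = "".join(_class_regex(p) for p in pattern.positions)
        return re.compile(f"(?=({body}))")
    idx, lo, hi = pattern.spacer
    left = "".join(_class_regex(p) for p in pattern.positions[:idx])
    right = "".join(_class_regex(p) for p in pattern.positions[idx:])
    # lazy quantifier -> shortest qualifying spacer per start position
    return re.compile(f"(?=({left})([ACGT]{{{lo},{hi}}}?)({right}))")


def _scan_one_strand(
    sequence: str,
    pattern: MotifPattern,
    spacer_policy: str,
) -> list[tuple[int, int, int | None]]:
    """(start, end, spacer_length) triples on the given sequence text."""
    out: list[tuple[int, int, int | None]] = []
    if pattern.spacer is None or spacer_policy == "shortest":
        rx = _pattern_regexes(pattern)
        for m in rx.finditer(sequence):
            if pattern.spacer is None:
                out.append((m.start(), m.start() + pattern.n_fixed, None))
            else:
                gap = len(m.group(2))
                out.append((m.start(), m.start() + pattern.n_fixed + gap, gap))
        return out
    # all-spacers policy: one sub-scan per fixed gap length
    idx, lo, hi = pattern.spacer
    left = "".join(_class_regex(p) for p in pattern.positions[:idx])
    right = "".join(_class_regex(p) for p in pattern.positions[idx:])
    for gap in range(lo, hi + 1):
        rx = re.compile(f"(?=({left})[ACGT]{{{gap}}}({right}))")
        for m in rx.finditer(sequence):
            out.append((m.start(), m.start() + pattern.n_fixed + gap, gap))
    out.sort()
    return out


def reverse_complement(sequence: str) -> str:
    return sequence.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]


def scan(
    sequence: str,
    pattern: MotifPattern,
    strands: Literal["forward", "reverse", "both"] = "both",
    chromosome: str = "",
    spacer_policy: Literal["shortest", "all"] = "shortest",
) -> list[MotifHit]:
    """All matches of a pattern in a nucleotide sequence.

    Reverse-strand matches are found by scanning the reverse complement
    and mapping coordinates back.  For self-reverse-complementary
    patterns scanned on both strands, coordinate-identical forward and
    reverse hits are collapsed to a single forward-strand hit.
    """
    if strands not in ("forward", "reverse", "both"):
        raise ConfigError(f"unknown strand selection {strands!r}")
    seq = sequence.upper()
    n = len(seq)
    hits: list[MotifHit] = []
    if strands in ("forward", "both"):
        for s, e, gap in _scan_one_strand(seq, pattern, spacer_policy):
            hits.append(
                MotifHit(
                    pattern_name=pattern.name,
                    chromosome=chromosome,
                    start=s,
                    end=e,
                    strand=FORWARD,
                    matched_sequence=seq[s:e],
                    spacer_length=gap,
                )
            )
    if strands in ("reverse", "both"):
        rc = reverse_complement(seq)
        for s, e, gap in _scan_one_strand(rc, pattern, spacer_policy):
            fs, fe = n - e, n - s
            hits.append(
                MotifHit(
                    pattern_name=pattern.name,
                    chromosome=chromosome,
                    start=fs,
                    end=fe,
                    strand=REVERSE,
                    matched_sequence=seq[fs:fe],
                    spacer_length=gap,
                )
            )
    if strands == "both" and pattern.is_self_reverse_complement:
        seen: dict[tuple[int, int], MotifHit] = {}
        for h in sorted(hits, key=lambda h: (h.start, h.end, h.strand)):
            seen.setdefault((h.start, h.end), h)  # "+" sorts before "-"
        hits = list(seen.values())
    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return hits


def scan_genome(
    sequences: Mapping[str, str],
    patterns: Iterable[MotifPattern],
    strands: Literal["forward", "reverse", "both"] = "both",
    spacer_policy: Literal["shortest", "all"] = "shortest",
) -> list[MotifHit]:
    """Scan every chromosome with every pattern."""
    hits: list[MotifHit] = []
    for chrom, seq in sequences.items():
        for pattern in patterns:
            hits.extend(
                scan(seq, pattern, strands=strands, chromosome=chrom,
                     spacer_policy=spacer_policy)
            )
    return hits


# ---------------------------------------------------------------------------
# context assignment
# ---------------------------------------------------------------------------

def assign_context(
    hits: Iterable[MotifHit],
    annotation: GenomeAnnotation,
    upstream_window: int = 1000,
) -> list[MotifHit]:
    """Label each hit by its relationship to the nearest gene(s).

    A hit inside a gene is ``inside``.  An intergenic hit within
    ``upstream_window`` bp of the 5' start of exactly one flanking gene
    (strand-aware, truncated at the neighbouring gene by construction)
    is ``upstream-of`` that gene; within the upstream regions of both
    flanking genes (an RF pair's shared interval) it is ``intergenic``
    with both genes listed; otherwise it is ``downstream-of`` the
    nearest flanking gene.
    """
    out: list[MotifHit] = []
    for hit in hits:
        genes = annotation.chromosomes.get(hit.chromosome)
        if genes is None:
            raise ValidationError(
                f"hit on unknown chromosome {hit.chromosome!r}"
            )
        out.append(replace(hit, context=_hit_context(hit, genes, upstream_window)))
    return out


def _hit_context(
    hit: MotifHit, genes: Sequence[Gene], upstream_window: int
) -> HitContext:
    inside = [g for g in genes if g.start < hit.end and hit.start < g.end]
    if inside:
        return HitContext(kind="inside", gene_ids=(inside[0].id,), distance=0)

    left = None
    right = None
    for g in genes:
        if g.end <= hit.start:
            left = g
        elif g.start >= hit.end and right is None:
            right = g
    upstream: list[tuple[int, Gene]] = []
    # right gene on forward strand: its promoter region extends left of its start
    if right is not None and right.strand == FORWARD:
        dist = right.start - hit.end
        if dist < upstream_window:
            upstream.append((dist, right))
    # left gene on reverse strand: promoter region extends right of its end
    if left is not None and left.strand == REVERSE:
        dist = hit.start - left.end
        if dist < upstream_window:
            upstream.append((dist, left))
    if len(upstream) == 2:
        return HitContext(
            kind="intergenic",
            gene_ids=(left.id, right.id),
            distance=min(d for d, _ in upstream),
        )
    if len(upstream) == 1:
        dist, gene = upstream[0]
        return HitContext(kind="upstream-of", gene_ids=(gene.id,), distance=dist)
    # downstream of the nearest flanking gene
    candidates: list[tuple[int, Gene]] = []
    if left is not None:
        candidates.append((hit.start - left.end, left))
    if right is not None:
        candidates.append((right.start - hit.end, right))
    if not candidates:
        return HitContext(kind="intergenic", gene_ids=(), distance=0)
    dist, gene = min(candidates, key=lambda t: t[0])
    return HitContext(kind="downstream-of", gene_ids=(gene.id,), distance=dist)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_hits_bed(hits: Iterable[MotifHit], path: str) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.chromosome}\t{h.start}\t{h.end}\t{h.pattern_name}\t0\t{h.strand}\n"
            )


def write_hits_tsv(hits: Iterable[MotifHit], path: str) -> None:
    """TSV with 1-based inclusive coordinates (report dialect)."""
    with open(path, "w") as fh:
        fh.write(
            "pattern\tchromosome\tstart\tend\tstrand\tmatched_sequence\t"
            "spacer_length\tcontext\tcontext_genes\tdistance\n"
        )
        for h in hits:
            ctx = h.context
            fh.write(
                f"{h.pattern_name}\t{h.chromosome}\t{h.start + 1}\t{h.end}\t"
                f"{h.strand}\t{h.matched_sequence}\t"
                f"{'' if h.spacer_length is None else h.spacer_length}\t"
                f"{ctx.kind if ctx else ''}\t"
                f"{','.join(ctx.gene_ids) if ctx else ''}\t"
                f"{ctx.distance if ctx else ''}\n"
            )
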