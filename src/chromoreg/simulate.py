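"""Synthetic genomes with controlled co-regulation structure.

Generates a FASTA + GFF3 + DE-call table triple whose statistical
structure is fully specified: gene/intergenic lengths, strand
composition, U/D/O state frequencies or exact counts, planted concordant
clusters (optionally flanked by a tRNA gene acting as a putative
insulator), subtelomeric low-expression zones, planted motif instances
in intergenic sequence, and directly planted 2x2 contingency structure
over adjacent pairs.  A ``SimTruth`` record carries the ground truth so
every downstream stage can be tested for exact recovery.

Everything is deterministic under ``(config, seed)``: the same config
yields byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .expression import DeRecord, StateSequence, build_state_sequences, state_map
from .genome import (
    FORWARD,
    REVERSE,
    Gene,
    GenomeAnnotation,
    adjacent_pairs,
    write_gff3,
)
from .motifs import REGISTRY, MotifPattern
from .pairs import ContingencyTable2x2, classify_pairs


@dataclass(frozen=True)
class LengthDist:
    """Truncated-normal bp length model (clipped below at ``minimum``)."""

    mean: float
    sd: float
    minimum: int

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        x = rng.normal(self.mean, self.sd, size=n)
        return np.maximum(np.rint(x).astype(int), self.minimum)


@dataclass(frozen=True)
class PlantedCluster:
    """A concordant cluster planted at a gene-index range.

    ``n_concordant`` genes take the cluster's direction starting from the
    centromere-proximal (left) edge; the remaining ``length - n_concordant``
    genes stay constitutive.  ``with_trna_flank`` retypes the gene
    immediately downstream (right) of the cluster as a tRNA.
    """

    chromosome_index: int
    start_index: int
    length: int = 6
    direction: str = "up"
    n_concordant: int | None = None  # default: all `length` genes
    with_trna_flank: bool = False


@dataclass(frozen=True)
class PlantedMotif:
    """A motif instance written into intergenic sequence.

    ``position`` is a bp offset on the chromosome, or ``None`` with
    ``pair_index`` set to centre the instance in the intergenic interval
    after gene ``pair_index`` (0-based within the chromosome).
    """

    pattern_name: str
    chromosome_index: int
    position: int | None = None
    pair_index: int | None = None


@dataclass
class SimConfig:
    n_chromosomes: int = 8
    genes_per_chromosome: int | Sequence[int] = 100
    gene_length: LengthDist = LengthDist(900.0, 200.0, 200)
    intergenic_length: LengthDist = LengthDist(250.0, 80.0, 60)
    telomere_gap: int = 2000
    p_forward: float = 0.5
    fixed_strands: Sequence[Sequence[str]] | None = None
    state_frequencies: tuple[float, float] | None = None  # (p_U, p_D)
    state_counts: tuple[int, int] | None = None  # exact genome-wide (n_U, n_D)
    explicit_states: Sequence[Sequence[str]] | None = None
    planted_clusters: Sequence[PlantedCluster] = field(default_factory=tuple)
    planted_motifs: Sequence[PlantedMotif] = field(default_factory=tuple)
    subtelomeric_zone: tuple[int, float] | None = None  # (n_genes_per_end, scale)
    with_sequence: bool = True  # False skips FASTA synthesis (stats-only genomes)
    seed: int = 0

    def gene_counts(self) -> list[int]:
        if isinstance(self.genes_per_chromosome, int):
            return [self.genes_per_chromosome] * self.n_chromosomes
        counts = list(self.genes_per_chromosome)
        if len(counts) != self.n_chromosomes:
            raise ConfigError(
                f"genes_per_chromosome lists {len(counts)} chromosomes, "
                f"config says {self.n_chromosomes}"
            )
        return counts


@dataclass
class SimTruth:
    """Ground truth for recovery tests."""

    states: dict[str, str]
    cluster_spans: list[dict]
    motif_coords: list[dict]
    pair_orientations: dict[str, str]  # "left_id|right_id" -> orientation
    contingency: ContingencyTable2x2
    n_excluded: int


@dataclass
class SimBundle:
    annotation: GenomeAnnotation
    sequences: dict[str, str]
    de_table: pd.DataFrame
    truth: SimTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate(config: SimConfig) -> SimBundle:
    """Realise a config into annotation + sequences + DE table + truth."""
    rng = np.random.default_rng(config.seed)
    counts = config.gene_counts()
    _validate_config(config, counts)

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chromosomes: dict[str, list[Gene]] = {}
    gene_ids_by_chrom: list[list[str]] = []

    for ci, (chrom, n) in enumerate(zip(chrom_names, counts)):
        glens = config.gene_length.sample(rng, n)
        gaps = config.intergenic_length.sample(rng, n)
        if config.fixed_strands is not None:
            strands = list(config.fixed_strands[ci])
            if len(strands) != n:
                raise ConfigError(
                    f"{chrom}: fixed_strands lists {len(strands)} strands for {n} genes"
                )
        else:
            strands = [
                FORWARD if u < config.p_forward else REVERSE
                for u in rng.random(n)
            ]
        genes = []
        ids = []
        pos = config.telomere_gap
        for i in range(n):
            gid = f"g{ci + 1}_{i + 1:05d}"
            genes.append(
                Gene(
                    id=gid,
                    chromosome=chrom,
                    start=pos,
                    end=pos + int(glens[i]),
                    strand=strands[i],
                )
            )
            ids.append(gid)
            pos += int(glens[i]) + int(gaps[i])
        chromosomes[chrom] = genes
        gene_ids_by_chrom.append(ids)

    states_by_chrom = _assign_states(config, counts, gene_ids_by_chrom, rng)

    # planted clusters: state override + optional tRNA flank
    cluster_spans = []
    for pc in config.planted_clusters:
        chrom = chrom_names[pc.chromosome_index]
        genes = chromosomes[chrom]
        n_conc = pc.n_concordant if pc.n_concordant is not None else pc.length
        state = "U" if pc.direction == "up" else "D"
        for j in range(pc.start_index, pc.start_index + pc.length):
            offset = j - pc.start_index
            states_by_chrom[pc.chromosome_index][j] = (
                state if offset < n_conc else "O"
            )
        if pc.with_trna_flank:
            fi = pc.start_index + pc.length
            if fi >= len(genes):
                raise ConfigError(
                    f"cluster on {chrom} has no downstream gene for a tRNA flank"
                )
            g = genes[fi]
            genes[fi] = Gene(
                id=g.id, chromosome=g.chromosome, start=g.start, end=g.end,
                strand=g.strand, feature_type="tRNA",
            )
            states_by_chrom[pc.chromosome_index][fi] = "O"
        cluster_spans.append(
            {
                "chromosome": chrom,
                "gene_ids": gene_ids_by_chrom[pc.chromosome_index][
                    pc.start_index : pc.start_index + pc.length
                ],
                "start": genes[pc.start_index].start,
                "end": genes[pc.start_index + pc.length - 1].end,
                "direction": pc.direction,
                "n_concordant": n_conc,
                "trna_gap": (
                    genes[pc.start_index + pc.length].start
                    - genes[pc.start_index + pc.length - 1].end
                    if pc.with_trna_flank
                    else None
                ),
            }
        )

    # subtelomeric zones force constitutive low expression at chromosome ends
    subtelomeric: set[str] = set()
    if config.subtelomeric_zone is not None:
        n_end, _scale = config.subtelomeric_zone
        for ci, ids in enumerate(gene_ids_by_chrom):
            for j in list(range(min(n_end, len(ids)))) + list(
                range(max(0, len(ids) - n_end), len(ids))
            ):
                states_by_chrom[ci][j] = "O"
                subtelomeric.add(ids[j])

    annotation = GenomeAnnotation(
        chromosomes=chromosomes,
        sequence_lengths=None,
    )

    de_table = _make_de_table(
        config, gene_ids_by_chrom, states_by_chrom, subtelomeric, rng
    )

    if config.with_sequence:
        sequences, motif_coords = _make_sequences(
            config, chrom_names, chromosomes, rng
        )
        annotation.sequence_lengths = {c: len(s) for c, s in sequences.items()}
    else:
        if config.planted_motifs:
            raise ConfigError("planted motifs require with_sequence=True")
        sequences, motif_coords = {}, []

    truth_states = {
        gid: st
        for ids, sts in zip(gene_ids_by_chrom, states_by_chrom)
        for gid, st in zip(ids, sts)
    }
    pairs = adjacent_pairs(annotation)
    table, n_excluded = classify_pairs(pairs, truth_states)
    truth = SimTruth(
        states=truth_states,
        cluster_spans=cluster_spans,
        motif_coords=motif_coords,
        pair_orientations={
            f"{p.left.id}|{p.right.id}": p.orientation for p in pairs
        },
        contingency=table,
        n_excluded=n_excluded,
    )
    return SimBundle(
        annotation=annotation,
        sequences=sequences,
        de_table=de_table,
        truth=truth,
        config=config,
    )


def _validate_config(config: SimConfig, counts: list[int]) -> None:
    if config.state_frequencies is not None:
        pu, pd_ = config.state_frequencies
        if not (0 <= pu <= 1 and 0 <= pd_ <= 1 and pu + pd_ <= 1):
            raise ConfigError(f"invalid state frequencies ({pu}, {pd_})")
    occupied: dict[int, set[int]] = {}
    for pc in config.planted_clusters:
        if not (0 <= pc.chromosome_index < config.n_chromosomes):
            raise ConfigError(f"cluster chromosome index {pc.chromosome_index} out of range")
        n = counts[pc.chromosome_index]
        if pc.start_index < 0 or pc.start_index + pc.length > n:
            raise ConfigError(
                f"cluster [{pc.start_index}, {pc.start_index + pc.length}) "
                f"outside chromosome of {n} genes"
            )
        span = set(range(pc.start_index, pc.start_index + pc.length))
        prev = occupied.setdefault(pc.chromosome_index, set())
        if prev & span:
            raise ConfigError("planted clusters overlap")
        prev |= span
    for pm in config.planted_motifs:
        if pm.pattern_name not in REGISTRY:
            raise ConfigError(f"unknown motif pattern {pm.pattern_name!r}")
        if (pm.position is None) == (pm.pair_index is None):
            raise ConfigError(
                "planted motif needs exactly one of position / pair_index"
            )


def _assign_states(
    config: SimConfig,
    counts: list[int],
    gene_ids_by_chrom: list[list[str]],
    rng: np.random.Generator,
) -> list[list[str]]:
    if config.explicit_states is not None:
        if [len(s) for s in config.explicit_states] != counts:
            raise ConfigError("explicit_states shape does not match gene counts")
        return [list(s) for s in config.explicit_states]

    states = [["O"] * n for n in counts]
    total = sum(counts)
    # genes reserved by planted structure are not part of random assignment
    reserved: set[tuple[int, int]] = set()
    planted_u = planted_d = 0
    for pc in config.planted_clusters:
        n_conc = pc.n_concordant if pc.n_concordant is not None else pc.length
        for j in range(pc.start_index, pc.start_index + pc.length):
            reserved.add((pc.chromosome_index, j))
        if pc.with_trna_flank:
            reserved.add((pc.chromosome_index, pc.start_index + pc.length))
        if pc.direction == "up":
            planted_u += n_conc
        else:
            planted_d += n_conc
    if config.subtelomeric_zone is not None:
        n_end = config.subtelomeric_zone[0]
        for ci, n in enumerate(counts):
            for j in list(range(min(n_end, n))) + list(range(max(0, n - n_end), n)):
                reserved.add((ci, j))

    free = [
        (ci, j)
        for ci, n in enumerate(counts)
        for j in range(n)
        if (ci, j) not in reserved
    ]

    if config.state_counts is not None:
        n_u, n_d = config.state_counts
        need_u = n_u - planted_u
        need_d = n_d - planted_d
        if need_u < 0 or need_d < 0:
            raise ConfigError(
                "planted clusters already exceed the requested exact state counts"
            )
        if need_u + need_d > len(free):
            raise ConfigError("exact state counts exceed unreserved gene count")
        chosen = rng.choice(len(free), size=need_u + need_d, replace=False)
        for k, idx in enumerate(chosen):
            ci, j = free[idx]
            states[ci][j] = "U" if k < need_u else "D"
    elif config.state_frequencies is not None:
        pu, pd_ = config.state_frequencies
        draws = rng.random(len(free))
        for (ci, j), u in zip(free, draws):
            if u < pu:
                states[ci][j] = "U"
            elif u < pu + pd_:
                states[ci][j] = "D"
    return states


def _make_de_table(
    config: SimConfig,
    gene_ids_by_chrom: list[list[str]],
    states_by_chrom: list[list[str]],
    subtelomeric: set[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = []
    scale = config.subtelomeric_zone[1] if config.subtelomeric_zone else 0.05
    for ids, sts in zip(gene_ids_by_chrom, states_by_chrom):
        for gid, st in zip(ids, sts):
            if gid in subtelomeric:
                v1 = round(float(rng.uniform(0.5, 3.0)) * scale, 4)
                lfc = 0.0
                v2 = v1
                q = round(float(rng.uniform(0.3, 1.0)), 4)
                sig = "no"
            elif st == "U":
                v1 = round(float(rng.uniform(5.0, 50.0)), 4)
                lfc = round(float(rng.uniform(1.0, 8.0)), 4)
                v2 = round(v1 * 2 ** lfc, 4)
                q = round(float(rng.uniform(1e-6, 0.01)), 8)
                sig = "yes"
            elif st == "D":
                v1 = round(float(rng.uniform(5.0, 50.0)), 4)
                lfc = round(float(rng.uniform(-8.0, -1.0)), 4)
                v2 = round(v1 * 2 ** lfc, 4)
                q = round(float(rng.uniform(1e-6, 0.01)), 8)
                sig = "yes"
            else:
                v1 = round(float(rng.uniform(5.0, 50.0)), 4)
                lfc = round(float(rng.uniform(-0.4, 0.4)), 4)
                v2 = round(v1 * 2 ** lfc, 4)
                q = round(float(rng.uniform(0.2, 1.0)), 4)
                sig = "no"
            rows.append((gid, v1, v2, lfc, q, sig))
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "value_1", "value_2", "log2(fold_change)",
            "q_value", "significant",
        ],
    )


def _sample_motif_instance(
    pattern: MotifPattern, rng: np.random.Generator
) -> str:
    """One concrete sequence matching the pattern (minimum spacer length)."""
    parts = []
    for i, pos in enumerate(pattern.positions):
        if pattern.spacer and i == pattern.spacer[0]:
            gap = pattern.spacer[1]
            parts.append("".join(rng.choice(list("ACGT"), size=gap)))
        bases = sorted(pos)
        parts.append(str(rng.choice(bases)))
    return "".join(parts)


def _make_sequences(
    config: SimConfig,
    chrom_names: list[str],
    chromosomes: dict[str, list[Gene]],
    rng: np.random.Generator,
) -> tuple[dict[str, str], list[dict]]:
    sequences: dict[str, str] = {}
    motif_coords: list[dict] = []
    planted_by_chrom: dict[int, list[tuple[int, str, str]]] = {}
    for pm in config.planted_motifs:
        pattern = REGISTRY[pm.pattern_name]
        instance = _sample_motif_instance(pattern, rng)
        genes = chromosomes[chrom_names[pm.chromosome_index]]
        if pm.position is not None:
            pos = pm.position
        else:
            left = genes[pm.pair_index]
            right = genes[pm.pair_index + 1]
            gap = right.start - left.end
            if gap < len(instance):
                raise ConfigError(
                    f"intergenic interval after gene {pm.pair_index} on "
                    f"{chrom_names[pm.chromosome_index]} too short "
                    f"({gap} bp) for motif {pm.pattern_name} ({len(instance)} bp)"
                )
            pos = left.end + (gap - len(instance)) // 2
        planted_by_chrom.setdefault(pm.chromosome_index, []).append(
            (pos, instance, pm.pattern_name)
        )
    for ci, chrom in enumerate(chrom_names):
        genes = chromosomes[chrom]
        length = (genes[-1].end if genes else 0) + config.telomere_gap
        seq = rng.choice(list("ACGT"), size=length)
        placed: list[tuple[int, int]] = []
        for pos, instance, pname in sorted(planted_by_chrom.get(ci, [])):
            end = pos + len(instance)
            if pos < 0 or end > length:
                raise ConfigError(f"planted motif at {pos} outside {chrom}")
            if any(pos < pe and ps < end for ps, pe in placed):
                raise ConfigError(f"planted motifs collide on {chrom} at {pos}")
            seq[pos:end] = list(instance)
            placed.append((pos, end))
            motif_coords.append(
                {
                    "pattern": pname,
                    "chromosome": chrom,
                    "start": pos,
                    "end": end,
                    "sequence": instance,
                }
            )
        sequences[chrom] = "".join(seq)
    return sequences, motif_coords


# ---------------------------------------------------------------------------
# contingency planting
# ---------------------------------------------------------------------------

def plant_contingency(
    table: ContingencyTable2x2,
    n_excluded: int,
    base_config: SimConfig | None = None,
) -> SimConfig:
    """Config for a genome whose pair classification equals ``table`` exactly.

    Prefers a single chromosome built as alternating U/D runs (providing
    the concordant pairs and the run-junction discordant pairs) followed
    by a constitutive tail (providing the OO pairs); RF orientations are
    placed greedily on non-adjacent pairs.  When the single-chain RF
    constraint is infeasible, falls back to a compact multi-chromosome
    layout of 2-gene islands.
    """
    base = base_config or SimConfig()
    layout = _single_chain_layout(table, n_excluded)
    if layout is None:
        layout = _island_layout(table, n_excluded)
    states, strands = layout
    return SimConfig(
        n_chromosomes=len(states),
        genes_per_chromosome=[len(s) for s in states],
        gene_length=base.gene_length,
        intergenic_length=base.intergenic_length,
        telomere_gap=base.telomere_gap,
        fixed_strands=strands,
        explicit_states=states,
        with_sequence=base.with_sequence,
        seed=base.seed,
    )


def _single_chain_layout(
    table: ContingencyTable2x2, n_excluded: int
) -> tuple[list[list[str]], list[list[str]]] | None:
    a, b, c, d, e = table.a, table.b, table.c, table.d, n_excluded
    n_conc, n_disc = a + b, c + d
    if n_conc == 0 and n_disc == 0:
        states = ["O"] * (e + 1 if e else 1)
        return [states], [[FORWARD] * len(states)]
    if n_disc == 0 and e > 0:
        return None  # a non-O block next to an O block always makes a discordant pair
    # number of alternating U/D runs: junctions give n_disc discordants,
    # minus one consumed by the junction into the O tail when e > 0
    n_runs = n_disc + 1 - (1 if e > 0 else 0)
    if n_runs < 1:
        return None
    # spread concordant pairs across runs: run of length L gives L-1 pairs
    lengths = [1 + n_conc // n_runs] * n_runs
    for i in range(n_conc % n_runs):
        lengths[i] += 1
    states: list[str] = []
    for i, L in enumerate(lengths):
        states.extend(["U" if i % 2 == 0 else "D"] * L)
    if e > 0:
        states.extend(["O"] * (e + 1))
    # classify chain pairs, then place RF greedily on non-adjacent pairs
    classes = []
    for s1, s2 in zip(states, states[1:]):
        if s1 == "O" and s2 == "O":
            classes.append("excluded")
        elif s1 == s2:
            classes.append("concordant")
        else:
            classes.append("discordant")
    need = {"concordant": a, "discordant": c}
    rf = [False] * len(classes)
    for i, cls in enumerate(classes):
        if cls in need and need[cls] > 0 and not (i > 0 and rf[i - 1]):
            rf[i] = True
            need[cls] -= 1
    if need["concordant"] or need["discordant"]:
        return None
    strands = [FORWARD] * len(states)
    for i, flag in enumerate(rf):
        if flag:
            strands[i] = REVERSE
            strands[i + 1] = FORWARD
    return [states], [strands]


def _island_layout(
    table: ContingencyTable2x2, n_excluded: int
) -> tuple[list[list[str]], list[list[str]]]:
    states: list[list[str]] = []
    strands: list[list[str]] = []
    for _ in range(table.a):  # concordant & common: 2-gene RF islands
        states.append(["U", "U"])
        strands.append([REVERSE, FORWARD])
    if table.b:  # concordant & different: one tandem U run
        states.append(["U"] * (table.b + 1))
        strands.append([FORWARD] * (table.b + 1))
    for _ in range(table.c):  # discordant & common
        states.append(["U", "O"])
        strands.append([REVERSE, FORWARD])
    if table.d:  # discordant & different: alternating U/O chain
        chain = ["U" if i % 2 == 0 else "O" for i in range(table.d + 1)]
        states.append(chain)
        strands.append([FORWARD] * len(chain))
    if n_excluded:
        states.append(["O"] * (n_excluded + 1))
        strands.append([FORWARD] * (n_excluded + 1))
    if not states:
        states, strands = [["O"]], [[FORWARD]]
    return states, strands


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_bundle(bundle: SimBundle, out_dir: str) -> dict[str, str]:
    """Write genome.fa / genes.gff3 / de_table.tsv / truth.json; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "genome.fa"
    with open(fasta, "w") as fh:
        for chrom, seq in bundle.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    gff = out / "genes.gff3"
    write_gff3(bundle.annotation, str(gff))
    de = out / "de_table.tsv"
    bundle.de_table.to_csv(de, sep="\t", index=False)
    truth = out / "truth.json"
    with open(truth, "w") as fh:
        json.dump(
            {
                "states": bundle.truth.states,
                "cluster_spans": bundle.truth.cluster_spans,
                "motif_coords": bundle.truth.motif_coords,
                "pair_orientations": bundle.truth.pair_orientations,
                "contingency": asdict(bundle.truth.contingency),
                "n_excluded": bundle.truth.n_excluded,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return {
        "fasta": str(fasta),
        "gff3": str(gff),
        "de_table": str(de),
        "truth": str(truth),
    }


def paper_scale_config(seed: int = 0, planted: bool = True) -> SimConfig:
    """The study-scale composition: 8 chromosomes, 5,162 genes, exactly
    323 up- and 245 down-regulated, and (optionally) three planted 6-gene
    up-regulated clusters with tRNA flanks, mirroring the two clusters on
    chromosome 1 and one on chromosome 7."""
    counts = [808, 704, 672, 654, 632, 610, 582, 500]
    assert sum(counts) == 5162
    clusters = (
        (
            PlantedCluster(0, 510, 6, "up", with_trna_flank=True),
            PlantedCluster(0, 540, 6, "up", n_concordant=4, with_trna_flank=True),
            PlantedCluster(6, 420, 6, "up", n_concordant=4),
        )
        if planted
        else ()
    )
    return SimConfig(
        n_chromosomes=8,
        genes_per_chromosome=counts,
        state_counts=(323, 245),
        planted_clusters=clusters,
        subtelomeric_zone=(8, 0.05),
        seed=seed,
    )
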