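"""Sliding-window detection of concordantly transcribed gene clusters.

A window of ``k`` consecutive genes (default 6) qualifies as concordant
when at least ``m`` of them (default 4) are differentially regulated in
the same direction and none in the opposite direction::

    (n_U >= m and n_D == 0) or (n_D >= m and n_U == 0)

The genome-wide concordant fraction (qualifying windows / all windows,
windows confined within chromosomes) is tested against a permutation
null: in each iteration the per-chromosome gene lists are joined, the
joined state list is uniformly shuffled, and the concordant fraction of
the shuffled list's sliding windows recomputed.  The p-value is the
fraction of iterations whose null statistic reaches the observed one.
The null preserves the exact U/D/O multiset — it asks whether the
*ordering* of expression states along chromosomes is random, not whether
the state counts themselves are.

Qualifying windows of the same direction that overlap are merged into
reportable clusters; constitutive genes inside a cluster are absorbed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, ValidationError
from .expression import StateSequence
from .genome import Gene, GenomeAnnotation

TIE_RULES = ("greater_or_equal", "strictly_greater")

_STATE_CODE = {"O": 0, "U": 1, "D": 2}


@dataclass(frozen=True)
class WindowSpec:
    """Window length ``k`` and minimum concordant count ``m``."""

    k: int = 6
    m: int = 4

    def __post_init__(self) -> None:
        if not (1 <= self.m <= self.k):
            raise ConfigError(f"window spec requires 1 <= m <= k, got k={self.k} m={self.m}")


@dataclass(frozen=True)
class PermutationResult:
    observed_fraction: float
    n_iterations: int
    exceedances: int
    p_value: float
    tie_rule: str
    seed: int
    null_mean: float
    null_sd: float
    plus_one: bool = False


@dataclass
class ClusterCall:
    """A merged run of qualifying windows, reported as one cluster."""

    chromosome: str
    gene_ids: list[str]
    span: tuple[int, int]
    direction: str  # "up" | "down"
    n_concordant: int
    nearest_trna_distance: int | None = None


def encode_states(states: Sequence[str]) -> np.ndarray:
    return np.array([_STATE_CODE[s] for s in states], dtype=np.int8)


def _window_sums(binary: np.ndarray, k: int) -> np.ndarray:
    """Sliding sums of width k along the last axis of a 0/1 array."""
    cs = np.cumsum(binary, axis=-1, dtype=np.int32)
    out = cs[..., k - 1 :].copy()
    out[..., 1:] -= cs[..., :-k]
    return out


def window_counts(states: StateSequence, spec: WindowSpec) -> list[tuple[int, int, int, int]]:
    """(position, n_U, n_D, n_O) for every sliding window, step 1."""
    n = len(states)
    if n < spec.k:
        return []
    codes = encode_states(states.states)
    su = _window_sums((codes == 1).astype(np.int8), spec.k)
    sd = _window_sums((codes == 2).astype(np.int8), spec.k)
    return [
        (i, int(su[i]), int(sd[i]), spec.k - int(su[i]) - int(sd[i]))
        for i in range(n - spec.k + 1)
    ]


def is_concordant(n_u: int, n_d: int, spec: WindowSpec) -> bool:
    """The window predicate: >= m one-direction calls, none opposite."""
    return (n_u >= spec.m and n_d == 0) or (n_d >= spec.m and n_u == 0)


def _concordant_flags(codes: np.ndarray, spec: WindowSpec) -> np.ndarray:
    su = _window_sums(codes == 1, spec.k)
    sd = _window_sums(codes == 2, spec.k)
    return ((su >= spec.m) & (sd == 0)) | ((sd >= spec.m) & (su == 0))


def concordant_fraction(
    sequences: Iterable[StateSequence], spec: WindowSpec
) -> float:
    """Qualifying-window fraction over all chromosomes' sliding windows."""
    n_windows = 0
    n_qualifying = 0
    for seq in sequences:
        if len(seq) < spec.k:
            continue
        flags = _concordant_flags(encode_states(seq.states), spec)
        n_windows += flags.size
        n_qualifying += int(flags.sum())
    if n_windows == 0:
        raise ValidationError(
            f"no window of {spec.k} genes exists anywhere in the genome"
        )
    return n_qualifying / n_windows


def permutation_test(
    sequences: Sequence[StateSequence],
    spec: WindowSpec = WindowSpec(),
    n_iterations: int = 100_000,
    seed: int = 0,
    tie_rule: str = "greater_or_equal",
    plus_one: bool = False,
) -> PermutationResult:
    """Gene-order shuffling test of the observed concordant fraction.

    The observed statistic is computed over per-chromosome windows; each
    null iteration shuffles the joined state list and computes the
    fraction over the joined list's windows (junction-spanning windows
    are irrelevant after shuffling).  Identical inputs and seed give
    bit-identical results.
    """
    if tie_rule not in TIE_RULES:
        raise ConfigError(f"unknown tie rule {tie_rule!r}; choose from {TIE_RULES}")
    if n_iterations < 1:
        raise ConfigError("n_iterations must be >= 1")

    observed = concordant_fraction(sequences, spec)
    joined = np.concatenate([encode_states(s.states) for s in sequences])
    n = joined.size
    n_windows = n - spec.k + 1
    if n_windows < 1:
        raise ValidationError("joined genome shorter than one window")

    rng = np.random.default_rng(seed)
    # chunk size fixed by n only, so the RNG stream (hence the result) does
    # not depend on how the iterations are batched on a given machine
    chunk = max(1, min(n_iterations, 4_000_000 // max(n, 1)))

    exceed = 0
    total = 0.0
    total_sq = 0.0
    done = 0
    while done < n_iterations:
        b = min(chunk, n_iterations - done)
        mat = np.tile(joined, (b, 1))
        rng.permuted(mat, axis=1, out=mat)
        flags = _concordant_flags(mat, spec)
        fracs = flags.sum(axis=1) / n_windows
        if tie_rule == "greater_or_equal":
            exceed += int((fracs >= observed).sum())
        else:
            exceed += int((fracs > observed).sum())
        total += float(fracs.sum())
        total_sq += float((fracs ** 2).sum())
        done += b

    null_mean = total / n_iterations
    null_var = max(0.0, total_sq / n_iterations - null_mean ** 2)
    if plus_one:
        p = (exceed + 1) / (n_iterations + 1)
    else:
        p = exceed / n_iterations
    return PermutationResult(
        observed_fraction=observed,
        n_iterations=n_iterations,
        exceedances=exceed,
        p_value=p,
        tie_rule=tie_rule,
        seed=seed,
        null_mean=null_mean,
        null_sd=float(np.sqrt(null_var)),
        plus_one=plus_one,
    )


def call_clusters(
    sequences: Iterable[StateSequence],
    spec: WindowSpec,
    annotation: GenomeAnnotation,
) -> list[ClusterCall]:
    """Merge overlapping qualifying windows of one direction into clusters.

    A cluster's gene set is the union of its member windows' genes (so
    constitutive genes inside are included); its direction is the shared
    direction of the member windows.  The nearest tRNA distance is the bp
    gap from the cluster span to the closest tRNA-typed gene on the same
    chromosome (0 if the tRNA overlaps the span; None if no tRNA exists).
    """
    clusters: list[ClusterCall] = []
    for seq in sequences:
        genes = annotation.chromosomes.get(seq.chromosome)
        if genes is None:
            raise ValidationError(f"chromosome {seq.chromosome} not in annotation")
        if len(seq) < spec.k:
            continue
        codes = encode_states(seq.states)
        su = _window_sums((codes == 1).astype(np.int8), spec.k)
        sd = _window_sums((codes == 2).astype(np.int8), spec.k)
        up = (su >= spec.m) & (sd == 0)
        down = (sd >= spec.m) & (su == 0)

        # gene index lookup for states (drop-missing policy can desync;
        # map by gene id instead of position)
        gene_by_id = {g.id: g for g in genes}

        for direction, flags, code in (("up", up, 1), ("down", down, 2)):
            i = 0
            nwin = flags.size
            while i < nwin:
                if not flags[i]:
                    i += 1
                    continue
                # extend over overlapping qualifying windows of this direction
                j = i
                last_window = i
                while j < nwin and (j <= last_window + spec.k - 1):
                    if flags[j]:
                        last_window = j
                    j += 1
                gi, gj = i, last_window + spec.k  # gene index range [gi, gj)
                # trim flanking constitutive genes: the cluster starts and
                # ends at a concordant gene (interior O genes stay absorbed)
                while gi < gj and codes[gi] != code:
                    gi += 1
                while gj > gi and codes[gj - 1] != code:
                    gj -= 1
                member_ids = seq.gene_ids[gi:gj]
                member_genes = [gene_by_id[g] for g in member_ids]
                span = (
                    min(g.start for g in member_genes),
                    max(g.end for g in member_genes),
                )
                n_conc = int((codes[gi:gj] == code).sum())
                clusters.append(
                    ClusterCall(
                        chromosome=seq.chromosome,
                        gene_ids=list(member_ids),
                        span=span,
                        direction=direction,
                        n_concordant=n_conc,
                        nearest_trna_distance=_nearest_trna_distance(span, genes),
                    )
                )
                i = last_window + 1
    return clusters


def _nearest_trna_distance(
    span: tuple[int, int], genes: Sequence[Gene]
) -> int | None:
    best: int | None = None
    for g in genes:
        if not g.is_trna:
            continue
        if g.end <= span[0]:
            dist = span[0] - g.end
        elif g.start >= span[1]:
            dist = g.start - span[1]
        else:
            dist = 0
        best = dist if best is None else min(best, dist)
    return best


def write_scan_report(result: PermutationResult, spec: WindowSpec, path: str) -> None:
    """One-row TSV summary of a permutation scan."""
    header = (
        "window_length\tmin_concordant\tobserved_fraction\tn_iterations\t"
        "exceedances\tp_value\ttie_rule\tseed\tnull_mean\tnull_sd\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        fh.write(
            f"{spec.k}\t{spec.m}\t{result.observed_fraction:.8g}\t"
            f"{result.n_iterations}\t{result.exceedances}\t{result.p_value:.8g}\t"
            f"{result.tie_rule}\t{result.seed}\t{result.null_mean:.8g}\t"
            f"{result.null_sd:.8g}\n"
        )


def write_cluster_reports(
    clusters: Sequence[ClusterCall],
    states: dict[str, str],
    fold_changes: dict[str, float],
    bed_path: str,
    tsv_path: str,
) -> None:
    """BED6 of cluster spans plus per-gene membership TSV."""
    with open(bed_path, "w") as fh:
        for c in clusters:
            name = f"{c.direction}:{c.n_concordant}"
            fh.write(f"{c.chromosome}\t{c.span[0]}\t{c.span[1]}\t{name}\t0\t.\n")
    with open(tsv_path, "w") as fh:
        fh.write("cluster\tchromosome\tdirection\tgene_id\tstate\tlog2fc\n")
        for idx, c in enumerate(clusters, 1):
            for gid in c.gene_ids:
                fh.write(
                    f"cluster{idx}\t{c.chromosome}\t{c.direction}\t{gid}\t"
                    f"{states.get(gid, 'O')}\t{fold_changes.get(gid, 0.0):.4g}\n"
                )
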