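"""Differential-expression calls and per-chromosome state sequences.

Each gene receives one of three states relative to a two-condition
contrast (here: xylose vs glucose medium):

* ``U`` — significantly up-regulated (significant call, log2FC > 0)
* ``D`` — significantly down-regulated (significant call, log2FC < 0)
* ``O`` — constitutive (everything else)

States derive from the DE table's own significance flag (CuffDiff-style
``yes``/``no``), not from re-thresholding q-values; a q-value fallback
(``q <= alpha``) exists for tables without a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, InputError, ValidationError
from .genome import GenomeAnnotation

logger = logging.getLogger(__name__)

STATES = ("U", "D", "O")

#: default column map, matching CuffDiff gene_exp.diff
DEFAULT_COLUMNS = {
    "gene_id": "gene_id",
    "value_1": "value_1",
    "value_2": "value_2",
    "log2_fold_change": "log2(fold_change)",
    "q_value": "q_value",
    "significant": "significant",
}

MISSING_POLICIES = ("treat-missing-as-O", "drop-missing", "error")


@dataclass(frozen=True)
class DeRecord:
    """One row of a differential-expression call table."""

    gene_id: str
    value_cond1: float
    value_cond2: float
    log2_fold_change: float
    q_value: float
    significant: bool


@dataclass
class StateSequence:
    """States of one chromosome's genes, in annotation order."""

    chromosome: str
    gene_ids: list[str]
    states: list[str]

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.states):
            raise ValidationError(
                f"{self.chromosome}: {len(self.gene_ids)} gene ids but "
                f"{len(self.states)} states"
            )

    def __len__(self) -> int:
        return len(self.states)


def read_de_table(
    path: str,
    columns: Mapping[str, str] | None = None,
    alpha: float | None = None,
) -> list[DeRecord]:
    """Read a CuffDiff-like TSV of differential-expression calls.

    ``columns`` remaps logical field names to the file's column names.
    If the table has no significance column, pass ``alpha`` to call
    significance as ``q_value <= alpha`` instead.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    try:
        df = pd.read_csv(path, sep="\t")
    except (OSError, pd.errors.ParserError) as exc:
        raise InputError(f"cannot read DE table {path}: {exc}") from exc

    required = ["gene_id", "value_1", "value_2", "log2_fold_change", "q_value"]
    if alpha is None:
        required.append("significant")
    for logical in required:
        if colmap[logical] not in df.columns:
            raise ConfigError(
                f"DE table {path} lacks column {colmap[logical]!r} "
                f"(logical field {logical!r}); available: {list(df.columns)}"
            )

    if df[colmap["gene_id"]].duplicated().any():
        dupes = df[colmap["gene_id"]][df[colmap["gene_id"]].duplicated()]
        raise ValidationError(
            f"duplicate gene ids in DE table: {sorted(set(dupes))[:5]} ..."
        )

    cols = {k: df[v] for k, v in colmap.items() if v in df.columns}
    records = []
    for i in range(len(df)):
        q = float(cols["q_value"].iloc[i])
        if alpha is not None:
            sig = q <= alpha
        else:
            sig = _parse_flag(cols["significant"].iloc[i])
        records.append(
            DeRecord(
                gene_id=str(cols["gene_id"].iloc[i]),
                value_cond1=float(cols["value_1"].iloc[i]),
                value_cond2=float(cols["value_2"].iloc[i]),
                log2_fold_change=float(cols["log2_fold_change"].iloc[i]),
                q_value=q,
                significant=sig,
            )
        )
    return records


def _parse_flag(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in {"yes", "true", "1"}


def assign_state(record: DeRecord) -> str:
    """Three-level call from one DE record (depends only on flag and FC sign)."""
    if record.significant and record.log2_fold_change > 0:
        return "U"
    if record.significant and record.log2_fold_change < 0:
        return "D"
    if record.significant and record.log2_fold_change == 0:
        logger.warning(
            "gene %s: significant with zero fold change; treated as O",
            record.gene_id,
        )
    return "O"


def build_state_sequences(
    annotation: GenomeAnnotation,
    records: Iterable[DeRecord],
    missing_policy: str = "treat-missing-as-O",
) -> list[StateSequence]:
    """One StateSequence per chromosome, aligned to annotation gene order.

    ``missing_policy`` controls genes absent from the DE table:
    ``treat-missing-as-O`` (default), ``drop-missing`` (gene removed from the
    sequence), or ``error``.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ConfigError(
            f"unknown missing policy {missing_policy!r}; choose from {MISSING_POLICIES}"
        )
    state_by_gene = {r.gene_id: assign_state(r) for r in records}
    sequences = []
    counts = {"U": 0, "D": 0, "O": 0}
    for chrom, genes in annotation.chromosomes.items():
        ids: list[str] = []
        states: list[str] = []
        for g in genes:
            if g.id not in state_by_gene:
                if missing_policy == "error":
                    raise ValidationError(
                        f"gene {g.id} ({chrom}) absent from the DE table"
                    )
                if missing_policy == "drop-missing":
                    continue
                state = "O"
            else:
                state = state_by_gene[g.id]
            ids.append(g.id)
            states.append(state)
            counts[state] += 1
        sequences.append(StateSequence(chromosome=chrom, gene_ids=ids, states=states))
    n = sum(counts.values())
    logger.info(
        "state sequences: %d genes (U=%d, D=%d, O=%d)",
        n, counts["U"], counts["D"], counts["O"],
    )
    return sequences


def state_map(sequences: Iterable[StateSequence]) -> dict[str, str]:
    """Flatten sequences to a gene_id -> state mapping."""
    return {
        gid: st
        for seq in sequences
        for gid, st in zip(seq.gene_ids, seq.states)
    }


def export_states_tsv(
    annotation: GenomeAnnotation,
    records: Iterable[DeRecord],
    path: str,
    missing_policy: str = "treat-missing-as-O",
) -> None:
    """Write (chromosome, gene_id, start, end, strand, state, log2FC) TSV."""
    recs = list(records)
    fc = {r.gene_id: r.log2_fold_change for r in recs}
    sequences = build_state_sequences(annotation, recs, missing_policy)
    gene_index = annotation.gene_index()
    rows = []
    for seq in sequences:
        for gid, st in zip(seq.gene_ids, seq.states):
            g = gene_index[gid]
            rows.append(
                (g.chromosome, gid, g.start, g.end, g.strand, st, fc.get(gid, 0.0))
            )
    pd.DataFrame(
        rows,
        columns=["chromosome", "gene_id", "start", "end", "strand", "state", "log2fc"],
    ).to_csv(path, sep="\t", index=False)
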