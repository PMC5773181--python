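"""Concordance-by-orientation association statistics for adjacent gene pairs.

Adjacent pairs are classified by joint expression state (unordered over
{U, D, O}) into *concordant* (UU, DD), *discordant* (UO, DO, UD) and
*excluded* (OO — uninformative, dropped), and cross-classified by whether
the pair shares a promoter-containing intergenic region ("common" = RF
orientation) or not ("different" = FF, RR, FR).  The resulting 2x2 table

                 common (RF)   different
    concordant        a            b
    discordant        c            d

is summarised by the likelihood ratio

    L = P(concordant | common) / P(concordant | different)
      = [a / (a + c)] / [b / (b + d)]

and by Fisher's exact test (conditional maximum-likelihood odds ratio
under the noncentral hypergeometric model, two-sided p by the
probability-ordering rule — the behaviour of the standard R
implementation).  The expected RF count under random orientation is
n/4 of the pairs with at least one differentially expressed gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import fisher_exact as _scipy_fisher
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

from .errors import UndefinedStatisticError, ValidationError
from .genome import PairRecord
from .segments import ClusterCall

#: canonical unordered joint states
JOINT_STATES = ("UU", "DD", "UO", "DO", "UD", "OO")

CONCORDANT = frozenset({"UU", "DD"})
DISCORDANT = frozenset({"UO", "DO", "UD"})


def joint_state(state_left: str, state_right: str) -> str:
    """Unordered joint state label (OU -> UO, OD -> DO, DU -> UD)."""
    order = {"U": 0, "D": 1, "O": 2}
    a, b = sorted((state_left, state_right), key=order.__getitem__)
    return a + b


def concordance_class(joint: str) -> str:
    if joint in CONCORDANT:
        return "concordant"
    if joint in DISCORDANT:
        return "discordant"
    if joint == "OO":
        return "excluded"
    raise ValidationError(f"unknown joint state {joint!r}")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a=conc/common, b=conc/different, c=disc/common, d=disc/different."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be non-negative")

    @property
    def n_common(self) -> int:
        return self.a + self.c

    @property
    def n_different(self) -> int:
        return self.b + self.d

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_lists(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float  # conditional MLE; nan when undefined (degenerate margin)
    p_two_sided: float
    sample_odds_ratio: float  # ad / (bc); nan when undefined


def classify_pairs(
    pairs: Iterable[PairRecord], states: Mapping[str, str]
) -> tuple[ContingencyTable2x2, int]:
    """Cross-classify adjacent pairs; OO pairs go only to the excluded count."""
    a = b = c = d = n_excluded = 0
    for pair in pairs:
        for gid in (pair.left.id, pair.right.id):
            if gid not in states:
                raise ValidationError(f"gene {gid} has no expression state")
        joint = joint_state(states[pair.left.id], states[pair.right.id])
        cls = concordance_class(joint)
        if cls == "excluded":
            n_excluded += 1
            continue
        common = pair.orientation == "RF"
        if cls == "concordant":
            if common:
                a += 1
            else:
                b += 1
        else:
            if common:
                c += 1
            else:
                d += 1
    return ContingencyTable2x2(a, b, c, d), n_excluded


def likelihood_ratio(table: ContingencyTable2x2) -> float:
    """L = [a/(a+c)] / [b/(b+d)]; undefined on zero denominators."""
    if table.n_common == 0 or table.n_different == 0 or table.b == 0:
        raise UndefinedStatisticError(
            f"likelihood ratio undefined for table {table}: zero denominator"
        )
    return (table.a / table.n_common) / (table.b / table.n_different)


def fisher_exact(table: ContingencyTable2x2) -> FisherResult:
    """Fisher's exact test with the conditional-MLE odds ratio.

    Degenerate margins (an all-zero row or column) give p = 1 and NaN
    odds ratios.
    """
    t = table.as_lists()
    row0, row1 = table.a + table.b, table.c + table.d
    col0, col1 = table.n_common, table.n_different
    if 0 in (row0, row1, col0, col1):
        return FisherResult(
            odds_ratio=math.nan, p_two_sided=1.0, sample_odds_ratio=math.nan
        )
    cmle = float(_scipy_odds_ratio(t, kind="conditional").statistic)
    p = float(_scipy_fisher(t, alternative="two-sided")[1])
    if table.b * table.c == 0:
        sample = math.inf if table.a * table.d > 0 else math.nan
    else:
        sample = (table.a * table.d) / (table.b * table.c)
    return FisherResult(odds_ratio=cmle, p_two_sided=p, sample_odds_ratio=sample)


def expected_rf_count(n_pairs_with_de: int) -> float:
    """Expected RF pairs among n informative pairs under random orientation."""
    if n_pairs_with_de < 0:
        raise ValidationError("pair count must be >= 0")
    return n_pairs_with_de / 4


def cluster_rf_explained_fraction(
    cluster: ClusterCall,
    pairs: Iterable[PairRecord],
    states: Mapping[str, str],
) -> float:
    """Fraction of a cluster's concordant genes explainable by shared
    intergenic regions.

    A concordant cluster gene counts as explained when it belongs to at
    least one RF pair whose partner is also a concordant member of the
    cluster (two outward-transcribed genes sharing one regulatory
    interval).
    """
    target = "U" if cluster.direction == "up" else "D"
    members = set(cluster.gene_ids)
    concordant = {g for g in members if states.get(g) == target}
    if not concordant:
        raise ValidationError(
            f"cluster on {cluster.chromosome} has no concordant gene"
        )
    explained: set[str] = set()
    for pair in pairs:
        if pair.orientation != "RF":
            continue
        li, ri = pair.left.id, pair.right.id
        if li in concordant and ri in concordant:
            explained.update((li, ri))
    return len(explained) / len(concordant)


def write_pairs_report(
    table: ContingencyTable2x2,
    n_excluded: int,
    path: str,
    n_rf_total: int | None = None,
) -> None:
    """TSV report: the 2x2 table, L, both odds ratios, p, RF counts."""
    try:
        lr = f"{likelihood_ratio(table):.6g}"
    except UndefinedStatisticError:
        lr = "NA"
    fr = fisher_exact(table)
    observed_rf = table.n_common
    expected_rf = expected_rf_count(table.total)
    with open(path, "w") as fh:
        fh.write(
            "concordant_common\tconcordant_different\tdiscordant_common\t"
            "discordant_different\tn_excluded_oo\tn_classified\t"
            "likelihood_ratio\todds_ratio_cmle\todds_ratio_sample\tp_two_sided\t"
            "observed_rf_informative\texpected_rf_informative\n"
        )
        fh.write(
            f"{table.a}\t{table.b}\t{table.c}\t{table.d}\t{n_excluded}\t"
            f"{table.total}\t{lr}\t{fr.odds_ratio:.6g}\t{fr.sample_odds_ratio:.6g}\t"
            f"{fr.p_two_sided:.6g}\t{observed_rf}\t{expected_rf:.6g}\n"
        )
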