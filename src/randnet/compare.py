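"""Two-sample Kolmogorov–Smirnov comparison of node attributes.

Real networks are compared against ensembles of random networks on their
shared numeric node attributes (typically centralities computed by an
external tool).  The distance between two attribute samples is the
two-sample K–S statistic: the maximum gap between the two empirical
cumulative distribution functions.  The ECDFs are never materialised — the
statistic is computed in a single merged pass over the two sorted samples,
accumulating normalised step heights and keeping the largest gap.

A distance of 0 means the empirical distributions are identical up to
replication (each observation is normalised by its sample size, so
[1, 2, 3] and [1, 1, 2, 2, 3, 3] are completely the same); a distance of 1
means every element of one sample exceeds every element of the other.
No p-value is computed: the distance itself is reported and interpreted
qualitatively.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .graph import Graph
from .io import (
    AttributeTable,
    ComparisonReport,
    ReportField,
    format_number,
)

__all__ = [
    "NetworkData",
    "KSResult",
    "ks_statistic",
    "shared_attributes",
    "attribute_values",
    "compare_single",
    "compare_multi",
]


@dataclass(frozen=True)
class NetworkData:
    """A named network with its node-attribute table."""

    name: str
    attributes: AttributeTable
    graph: Optional[Graph] = None


@dataclass(frozen=True)
class KSResult:
    """K–S distance between one real and one random network for one attribute."""

    real: str
    random: str
    attribute: str
    distance: float


def ks_statistic(
    a: Sequence[float], b: Sequence[float], normalization: str = "count"
) -> float:
    """Two-sample K–S distance: max ECDF gap, streaming over sorted samples.

    ``normalization="count"`` (default) is the standard ECDF: each
    observation contributes 1/(sample size).  ``normalization="value_sum"``
    instead lets each observation contribute value/(sum of the sample),
    which requires strictly positive sample sums.

    Ties across the two samples are resolved by advancing both cumulative
    sums over all elements equal to the current value before measuring the
    gap, the two-sided convention.  The result is in [0, 1], symmetric in
    the samples, and invariant under k-fold replication of either sample
    (count mode).
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if normalization not in ("count", "value_sum"):
        raise ValueError(f"unknown normalization {normalization!r}")
    sa, sb = sorted(a), sorted(b)
    if not (math.isfinite(sa[0]) and math.isfinite(sa[-1])
            and math.isfinite(sb[0]) and math.isfinite(sb[-1])):
        raise ValueError("samples must contain only finite values")
    na, nb = len(sa), len(sb)

    if normalization == "count":
        # integer tie counts with a cross-multiplied gap: exact 0 for
        # replicated samples, exact 1 for disjoint ordered supports
        i = j = 0
        best = 0
        while i < na or j < nb:
            if j >= nb or (i < na and sa[i] <= sb[j]):
                v = sa[i]
            else:
                v = sb[j]
            while i < na and sa[i] == v:
                i += 1
            while j < nb and sb[j] == v:
                j += 1
            best = max(best, abs(i * nb - j * na))
        return best / (na * nb)

    ta, tb = math.fsum(sa), math.fsum(sb)
    if ta <= 0 or tb <= 0:
        raise ValueError("value_sum normalization requires positive sample sums")
    i = j = 0
    ca = cb = 0.0
    best = 0.0
    while i < na or j < nb:
        if j >= nb or (i < na and sa[i] <= sb[j]):
            v = sa[i]
        else:
            v = sb[j]
        while i < na and sa[i] == v:
            ca += sa[i] / ta
            i += 1
        while j < nb and sb[j] == v:
            cb += sb[j] / tb
            j += 1
        best = max(best, abs(ca - cb))
    return best


def shared_attributes(tables: Sequence[AttributeTable]) -> List[str]:
    """Case-sensitive intersection of attribute names across all tables, sorted.

    Raises ``ValueError`` if no attribute is shared (attribute names are
    case-sensitive: ``Degree`` and ``degree`` are different attributes).
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 attribute tables to intersect")
    sets = [{a for row in t.values() for a in row} for t in tables]
    shared = set.intersection(*sets)
    if not shared:
        raise ValueError(
            "no attribute is shared by all selected networks; check the "
            "attribute names in the node tables (names are case-sensitive)"
        )
    return sorted(shared)


def attribute_values(table: AttributeTable, attr: str, name: str = "") -> List[float]:
    """All values of ``attr`` in a table; nodes lacking it are skipped with a
    warning (treating them as 0 would distort the ECDF)."""
    values, missing = [], 0
    for node, row in table.items():
        if attr in row:
            values.append(row[attr])
        else:
            missing += 1
    if missing:
        warnings.warn(
            f"{missing} node(s) missing attribute {attr!r}"
            + (f" in network {name!r}" if name else "")
            + "; skipped",
            stacklevel=2,
        )
    if not values:
        raise ValueError(f"no node carries attribute {attr!r}" + (f" in {name!r}" if name else ""))
    return values


def _distance_table(
    reals: Sequence[NetworkData],
    randoms: Sequence[NetworkData],
    attrs: Sequence[str],
    normalization: str,
) -> Dict[Tuple[str, str, str], float]:
    """K–S distance for every (real, random, attribute) triple."""
    out: Dict[Tuple[str, str, str], float] = {}
    for real in reals:
        for attr in attrs:
            va = attribute_values(real.attributes, attr, real.name)
            for rand in randoms:
                vb = attribute_values(rand.attributes, attr, rand.name)
                out[(real.name, rand.name, attr)] = ks_statistic(
                    va, vb, normalization=normalization
                )
    return out


def _check_inputs(
    reals: Sequence[NetworkData], randoms: Sequence[NetworkData], attrs: Sequence[str]
) -> None:
    if not randoms:
        raise ValueError("at least one random network is required")
    if not attrs:
        raise ValueError("at least one attribute must be selected")
    shared = set(
        shared_attributes([n.attributes for n in list(reals) + list(randoms)])
    )
    unknown = [a for a in attrs if a not in shared]
    if unknown:
        raise ValueError(f"attributes not shared by all networks: {unknown!r}")


def compare_single(
    real: NetworkData,
    randoms: Sequence[NetworkData],
    attrs: Sequence[str],
    normalization: str = "count",
) -> ComparisonReport:
    """Compare one real network against an ensemble of random networks.

    Report fields: the network names; per random network, the average
    distance across all attributes; per attribute, the most similar random
    network and its distance; and the full attribute-by-random distance
    matrix.
    """
    _check_inputs([real], randoms, attrs)
    attrs = list(attrs)
    dist = _distance_table([real], randoms, attrs, normalization)

    fields = [
        ReportField("real networks", [[real.name]]),
        ReportField("random networks", [[r.name] for r in randoms]),
    ]

    avg_rows = []
    for r in randoms:
        avg = _mean([dist[(real.name, r.name, a)] for a in attrs])
        avg_rows.append([r.name, format_number(avg)])
    fields.append(
        ReportField(
            "average distance between the real network and each random network, "
            "across all attributes",
            avg_rows,
        )
    )

    best_rows = []
    for a in attrs:
        best = min(randoms, key=lambda r: dist[(real.name, r.name, a)])
        best_rows.append(
            [a, best.name, format_number(dist[(real.name, best.name, a)])]
        )
    fields.append(
        ReportField(
            "most similar random network to the real network, for each attribute",
            best_rows,
        )
    )

    matrix_rows = [["attribute"] + [r.name for r in randoms]]
    for a in attrs:
        matrix_rows.append(
            [a] + [format_number(dist[(real.name, r.name, a)]) for r in randoms]
        )
    fields.append(
        ReportField(
            "distance between the real network and each random network, "
            "for each attribute",
            matrix_rows,
        )
    )
    return ComparisonReport(mode="single_real", fields=fields)


def compare_multi(
    reals: Sequence[NetworkData],
    randoms: Sequence[NetworkData],
    attrs: Sequence[str],
    normalization: str = "count",
) -> ComparisonReport:
    """Compare several real networks against a random ensemble (summary view).

    Report fields: the network names; per real network, the average distance
    (across all attributes) to its most similar random network; per (real
    network, attribute), the most similar random network and its distance;
    and the real-by-random distance matrix of attribute-averaged distances.
    """
    if len(reals) < 2:
        raise ValueError("multi-real comparison needs >= 2 real networks")
    _check_inputs(reals, randoms, attrs)
    attrs = list(attrs)
    dist = _distance_table(reals, randoms, attrs, normalization)

    def avg_dist(real: NetworkData, rand: NetworkData) -> float:
        return _mean([dist[(real.name, rand.name, a)] for a in attrs])

    fields = [
        ReportField("real networks", [[r.name] for r in reals]),
        ReportField("random networks", [[r.name] for r in randoms]),
    ]

    fields.append(
        ReportField(
            "average distance to the most similar random network, "
            "for each real network",
            [
                [real.name, format_number(min(avg_dist(real, r) for r in randoms))]
                for real in reals
            ],
        )
    )

    best_rows = []
    for real in reals:
        for a in attrs:
            best = min(randoms, key=lambda r: dist[(real.name, r.name, a)])
            best_rows.append(
                [real.name, a, best.name,
                 format_number(dist[(real.name, best.name, a)])]
            )
    fields.append(
        ReportField(
            "most similar random network for each real network and attribute",
            best_rows,
        )
    )

    matrix_rows = [["real network"] + [r.name for r in randoms]]
    for real in reals:
        matrix_rows.append(
            [real.name] + [format_number(avg_dist(real, r)) for r in randoms]
        )
    fields.append(
        ReportField(
            "real-random distance matrix "
            "(average distance across all attributes)",
            matrix_rows,
        )
    )
    return ComparisonReport(mode="multi_real", fields=fields)


def _mean(xs: Sequence[float]) -> float:
    return math.fsum(xs) / len(xs)
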