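"""Reported statistics of the eight published kinase-family PKFI sets.

The original PKFI study curated eight per-family inhibitor sets from
ChEMBL v25 and a public kinase-profiling panel and reported, for each
family, the member count, the positive/negative class counts and the
test-set ACC/MCC/AUROC of its GCN model. Those printed numbers are kept
here as a frozen reference table: the class counts feed the same
balance-statistic code path used for freshly built PKFI sets, and the
metric columns feed the metric-aggregation helpers, so the published
summary statistics (per-family balance, eight-family mean balance, mean
ACC, mean AUROC) can be recomputed from first principles at any time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pkfi import balance_ratio


@dataclass(frozen=True)
class FamilyBenchmark:
    group: str
    family: str
    members: int
    n_positive: int
    n_negative: int
    acc: float
    mcc: float
    auroc: float

    @property
    def balance(self) -> float:
        return balance_ratio(self.n_positive, self.n_negative)


#: Reported per-family counts and test metrics (eight published PKFI sets).
REPORTED_FAMILY_BENCHMARKS = (
    FamilyBenchmark("TK",   "EGFR", 4,  620, 808, 0.85, 0.70, 0.92),
    FamilyBenchmark("TK",   "JAK",  4, 1347, 877, 0.84, 0.64, 0.91),
    FamilyBenchmark("CAMK", "PIM",  3,  688, 628, 0.84, 0.68, 0.91),
    FamilyBenchmark("CAMK", "PKD",  3,   67, 462, 0.92, 0.16, 0.91),
    FamilyBenchmark("AGC",  "AKT",  3,  394, 772, 0.90, 0.79, 0.94),
    FamilyBenchmark("AGC",  "PKG",  2,   51, 396, 0.89, 0.31, 0.91),
    FamilyBenchmark("CMGC", "GSK",  2,  243, 657, 0.75, 0.28, 0.81),
    FamilyBenchmark("CMGC", "CLK",  4,  178, 418, 0.72, 0.20, 0.79),
)


def family_balance(family: str) -> float:
    """Balance (positives per negative) of one reported family set."""
    for row in REPORTED_FAMILY_BENCHMARKS:
        if row.family == family:
            return row.balance
    raise KeyError(f"unknown family {family!r}")


def mean_metric(metric: str) -> float:
    """Mean of one reported column ('balance', 'acc', 'mcc', 'auroc')."""
    values = [getattr(row, metric) for row in REPORTED_FAMILY_BENCHMARKS]
    return float(np.mean(values))
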