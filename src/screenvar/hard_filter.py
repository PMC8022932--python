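"""Seven-criterion hard filter on caller quality annotations.

A variant is removed when any of the exclusion expressions is true:

    QD < 2.0, MQ < 40.0, QUAL < 100, MQRankSum < -12.5,
    SOR > 4.0, FS > 60.0, ReadPosRankSum < -8.0

Inequalities are strict exactly as written, so boundary values pass, and
an absent metric can never fail its criterion (rank-sum annotations are
routinely missing; failing on absence would discard most genuine calls).
The same threshold set applies to SNVs and indels.
"""
from __future__ import annotations

from dataclasses import dataclass

from .variant_model import Variant, VariantQualityMetrics


@dataclass(frozen=True)
class FilterThresholds:
    qd_min: float = 2.0
    mq_min: float = 40.0
    qual_min: float = 100.0
    mqranksum_min: float = -12.5
    sor_max: float = 4.0
    fs_max: float = 60.0
    readpos_min: float = -8.0


@dataclass(frozen=True)
class FilterVerdict:
    failed_criteria: tuple[str, ...] = ()

    @property
    def passed(self) -> bool:
        return not self.failed_criteria


#: (criterion name, metric attribute, threshold attribute, direction)
#: direction "lt": fail when metric < threshold; "gt": fail when metric > threshold
CRITERIA = (
    ("QD", "QD", "qd_min", "lt"),
    ("MQ", "MQ", "mq_min", "lt"),
    ("QUAL", "QUAL", "qual_min", "lt"),
    ("MQRankSum", "MQRankSum", "mqranksum_min", "lt"),
    ("SOR", "SOR", "sor_max", "gt"),
    ("FS", "FS", "fs_max", "gt"),
    ("ReadPosRankSum", "ReadPosRankSum", "readpos_min", "lt"),
)


def evaluate_variant(
    metrics: VariantQualityMetrics, thresholds: FilterThresholds | None = None
) -> FilterVerdict:
    """Evaluate all seven criteria; the verdict lists every failing one."""
    t = thresholds or FilterThresholds()
    failed = []
    for name, attr, tattr, direction in CRITERIA:
        value = getattr(metrics, attr)
        if value is None:
            continue
        threshold = getattr(t, tattr)
        if (direction == "lt" and value < threshold) or (
            direction == "gt" and value > threshold
        ):
            failed.append(name)
    return FilterVerdict(tuple(failed))


def filter_callset(
    variants: list[Variant], thresholds: FilterThresholds | None = None
) -> tuple[list[Variant], list[tuple[Variant, FilterVerdict]]]:
    """Partition a callset into passed variants and (variant, verdict) failures.

    Every input variant lands in exactly one output; input order is
    preserved within each.
    """
    passed: list[Variant] = []
    failed: list[tuple[Variant, FilterVerdict]] = []
    for v in variants:
        verdict = evaluate_variant(v.metrics, thresholds)
        if verdict.passed:
            passed.append(v)
        else:
            failed.append((v, verdict))
    return passed, failed
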