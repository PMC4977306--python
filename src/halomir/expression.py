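"""qPCR relative expression (2^-ddCt) and RPM condition comparison.

Each assay carries replicate Ct values for the target and an internal
control (U6 for miRNAs, FNR1 for mRNAs) under two conditions. dCt is the
mean target Ct minus the mean internal-control Ct per condition; the fold
change is -ddCt = dCt(control) - dCt(salt) and relative expression is
2^(-ddCt). Significance comes from a two-sample t-test on the replicate
dCt values (Welch by default; the pooled-variance flavor is available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy import stats as _stats

ALPHA = 0.05


@dataclass
class QpcrRecord:
    """Replicate Ct values for one assay under two conditions."""

    assay: str
    target_ct: dict[str, list[float]]  # condition -> replicate Ct values
    control_ct: dict[str, list[float]]  # internal-control Ct values

    def delta_ct(self, condition: str) -> list[float]:
        """Per-replicate dCt (target - internal control), paired by replicate."""
        targets = self.target_ct[condition]
        controls = self.control_ct[condition]
        if len(targets) != len(controls):
            raise ValueError("replicate counts differ between target and control")
        return [t - c for t, c in zip(targets, controls)]


@dataclass
class ExpressionResult:
    assay: str
    delta_ct: dict[str, float]
    fold_change: float  # -ddCt = dCt(control) - dCt(treated)
    relative_expression: float  # 2^fold_change
    p_value: float
    significant: bool
    conditions: tuple[str, str] = ("control", "salt")


def delta_delta_ct(
    record: QpcrRecord,
    baseline: str = "control",
    treated: str = "salt",
    alpha: float = ALPHA,
    equal_var: bool = False,
) -> ExpressionResult:
    """Relative expression of one assay between two conditions.

    ``equal_var=False`` (default) runs Welch's t-test on replicate dCt
    values; ``True`` selects the pooled-variance Student's test.
    """
    for condition in (baseline, treated):
        if condition not in record.target_ct or condition not in record.control_ct:
            raise ValueError(f"missing Ct data for condition {condition!r}")
        if not record.control_ct[condition]:
            raise ValueError(f"missing internal control for condition {condition!r}")
    dct_base = record.delta_ct(baseline)
    dct_treat = record.delta_ct(treated)
    mean_base = sum(dct_base) / len(dct_base)
    mean_treat = sum(dct_treat) / len(dct_treat)
    fold_change = mean_base - mean_treat
    if len(dct_base) >= 2 and len(dct_treat) >= 2:
        p_value = float(
            _stats.ttest_ind(dct_base, dct_treat, equal_var=equal_var).pvalue
        )
    else:
        p_value = math.nan
    return ExpressionResult(
        assay=record.assay,
        delta_ct={baseline: mean_base, treated: mean_treat},
        fold_change=fold_change,
        relative_expression=2.0 ** fold_change,
        p_value=p_value,
        significant=bool(p_value <= alpha) if not math.isnan(p_value) else False,
        conditions=(baseline, treated),
    )


@dataclass
class RpmComparison:
    family: str
    baseline_rpm: float
    treated_rpm: float
    ratio: float  # treated / baseline; inf when baseline is 0 and treated > 0
    log2_ratio: float
    direction: str  # up / down / unchanged
    flagged: bool = False


def compare_rpm(
    rpm_per_library: Mapping[str, float],
    baseline: str = "control",
    treated: str = "salt",
    family: str = "",
    dead_band: float = 0.10,
) -> RpmComparison:
    """Linear and log2 RPM ratio with an up/down/unchanged call.

    Ratios within ``dead_band`` of 1 are called unchanged. A zero baseline
    with nonzero treated RPM is reported as infinity and flagged.
    """
    base = rpm_per_library.get(baseline, 0.0)
    treat = rpm_per_library.get(treated, 0.0)
    if base == 0.0:
        if treat == 0.0:
            return RpmComparison(family, 0.0, 0.0, 1.0, 0.0, "unchanged")
        return RpmComparison(family, base, treat, math.inf, math.inf, "up", flagged=True)
    ratio = treat / base
    log2_ratio = math.log2(ratio) if ratio > 0 else -math.inf
    if 1 - dead_band <= ratio <= 1 + dead_band:
        direction = "unchanged"
    elif ratio > 1:
        direction = "up"
    else:
        direction = "down"
    return RpmComparison(family, base, treat, ratio, log2_ratio, direction)


def read_ct_table(path) -> list[QpcrRecord]:
    """TSV columns: assay, condition, replicate, target_ct, control_ct."""
    records: dict[str, QpcrRecord] = {}
    with open(path) as handle:
        header = handle.readline().strip().split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in handle:
            if not line.strip():
                continue
            row = line.rstrip("\n").split("\t")
            assay = row[idx["assay"]]
            condition = row[idx["condition"]]
            record = records.setdefault(assay, QpcrRecord(assay, {}, {}))
            record.target_ct.setdefault(condition, []).append(float(row[idx["target_ct"]]))
            record.control_ct.setdefault(condition, []).append(float(row[idx["control_ct"]]))
    return list(records.values())


def write_expression_tsv(path, results: Sequence[ExpressionResult]) -> None:
    with open(path, "w") as handle:
        handle.write(
            "assay\tdct_baseline\tdct_treated\tfold_change\trelative_expression\tp_value\tsignificant\n"
        )
        for r in results:
            base, treat = r.conditions
            handle.write(
                f"{r.assay}\t{r.delta_ct[base]:.4f}\t{r.delta_ct[treat]:.4f}"
                f"\t{r.fold_change:.4f}\t{r.relative_expression:.4f}"
                f"\t{r.p_value:.4g}\t{'yes' if r.significant else 'no'}\n"
            )
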