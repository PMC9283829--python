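"""Accuracy accounting for fetal genotype calls.

Accuracies are reported as 100 * n_true / n_total, half-up rounded to one
decimal. Engines that only address a subset of loci (the haplotype path)
are scored over their classified loci; gap-filling engines (Bayesian,
combined) are scored over every locus in the category, so the two kinds of
rows legitimately carry different denominators.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .core_model import FetalCall, Genotype


def table1_accuracy(n_true: int, n_total: int) -> float:
    """Percent accuracy, half-up rounded to one decimal place."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_true <= n_total):
        raise ValueError("need 0 <= n_true <= n_total")
    pct = Decimal(100 * n_true) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def score_calls(
    calls: Sequence[FetalCall],
    truth: Mapping[tuple[str, int], Genotype],
    denominator: str = "all",
) -> pd.DataFrame:
    """Per-(category, variant-class) accuracy report against a truth set.

    ``denominator="all"`` counts every truth-covered locus (unclassified
    calls score as incorrect); ``"classified"`` restricts to loci the
    engine actually called. Loci absent from the truth set are excluded
    and counted in the ``n_missing_truth`` attribute of the result.
    """
    if denominator not in ("all", "classified"):
        raise ValueError("denominator must be 'all' or 'classified'")
    rows = []
    n_missing = 0
    for call in calls:
        loc = call.locus
        true_gt = truth.get((loc.chrom, loc.pos))
        if true_gt is None:
            n_missing += 1
            continue
        classified = call.genotype is not None
        if denominator == "classified" and not classified:
            continue
        rows.append(
            (
                loc.category,
                loc.vclass,
                classified and tuple(call.genotype) == tuple(true_gt),
            )
        )
    df = pd.DataFrame(rows, columns=["category", "vclass", "correct"])
    if df.empty:
        report = pd.DataFrame(columns=["category", "vclass", "n_true", "n_total", "accuracy"])
    else:
        grouped = (
            df.groupby(["category", "vclass"], as_index=False)
            .agg(n_true=("correct", "sum"), n_total=("correct", "size"))
        )
        grouped["accuracy"] = [
            table1_accuracy(int(t), int(n))
            for t, n in zip(grouped["n_true"], grouped["n_total"])
        ]
        report = grouped
    report.attrs["n_missing_truth"] = n_missing
    return report


def accuracy_of(report: pd.DataFrame, category: str, vclass: str = "SNV") -> float:
    """Convenience lookup of one accuracy cell from a score_calls report."""
    sel = report[(report["category"] == category) & (report["vclass"] == vclass)]
    if sel.empty:
        raise KeyError(f"no ({category}, {vclass}) row in report")
    return float(sel["accuracy"].iloc[0])
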