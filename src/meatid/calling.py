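"""Contamination and mislabelling calls from composition profiles.

A sample is called contaminated when the highest genus-level percentage
average fold is strictly below the purity threshold (default 98%).
Non-dominant genera at or above the trace threshold (default 2%) are
substantive contaminants; those below it are trace contaminants,
attributable to cross-contamination or database stringency rather than
substitution.  Mislabelling — the declared species' genus not being the
dominant genus — is a separate flag from contamination: a sample can be
mislabelled yet pass the purity rule.  Percentages are compared at full
precision; one-decimal display rounding plays no part in the calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .classify import CompositionProfile


@dataclass(frozen=True)
class CallThresholds:
    purity_threshold: float = 98.0
    trace_threshold: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.trace_threshold < self.purity_threshold <= 100:
            raise ValueError("need 0 < trace_threshold < purity_threshold <= 100")


@dataclass
class ContaminationCall:
    sample_id: str
    top_genus: str | None
    top_pct: float
    contaminated: bool
    substantive_contaminants: list[tuple[str, float]] = field(default_factory=list)
    trace_contaminants: list[tuple[str, float]] = field(default_factory=list)
    declared_genus: str | None = None
    mislabelled: bool | None = None
    failed: bool = False


def call_sample(
    profile: CompositionProfile,
    thresholds: CallThresholds = CallThresholds(),
    declared_genus: str | None = None,
) -> ContaminationCall:
    if profile.failed:
        return ContaminationCall(
            profile.sample_id, top_genus=None, top_pct=0.0, contaminated=False,
            declared_genus=declared_genus, failed=True,
        )
    top_genus, top_pct = profile.top
    substantive, trace = [], []
    for genus, pct in sorted(profile.entries.items(), key=lambda kv: (-kv[1], kv[0])):
        if genus == top_genus:
            continue
        (substantive if pct >= thresholds.trace_threshold else trace).append((genus, pct))
    return ContaminationCall(
        sample_id=profile.sample_id,
        top_genus=top_genus,
        top_pct=top_pct,
        contaminated=top_pct < thresholds.purity_threshold,
        substantive_contaminants=substantive,
        trace_contaminants=trace,
        declared_genus=declared_genus,
        mislabelled=None if declared_genus is None else declared_genus != top_genus,
    )


def call_batch(
    profiles: list[CompositionProfile],
    thresholds: CallThresholds = CallThresholds(),
    declared: dict[str, str] | None = None,
    categories: dict[str, str] | None = None,
) -> tuple[list[ContaminationCall], pd.DataFrame]:
    """Call every profile and tabulate contaminated counts per category.

    ``declared`` maps sample_id -> declared genus; ``categories`` maps
    sample_id -> product category (samples without one go to "all").
    Returns the calls and a (category, contaminated, total) table ready
    for proportion testing.
    """
    declared = declared or {}
    categories = categories or {}
    calls = [
        call_sample(p, thresholds, declared.get(p.sample_id)) for p in profiles
    ]
    counts: dict[str, list[int]] = {}
    for call in calls:
        cat = categories.get(call.sample_id, "all")
        k_n = counts.setdefault(cat, [0, 0])
        k_n[0] += int(call.contaminated)
        k_n[1] += 1
    summary = pd.DataFrame(
        [{"category": c, "contaminated": k, "total": n} for c, (k, n) in sorted(counts.items())],
        columns=["category", "contaminated", "total"],
    )
    return calls, summary


def calls_table(calls: list[ContaminationCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "sample_id": c.sample_id,
                "top_genus": c.top_genus,
                "top_pct": c.top_pct,
                "contaminated": c.contaminated,
                "substantive_contaminants": ";".join(f"{g}:{p:.2f}" for g, p in c.substantive_contaminants),
                "trace_contaminants": ";".join(f"{g}:{p:.2f}" for g, p in c.trace_contaminants),
                "declared_genus": c.declared_genus,
                "mislabelled": c.mislabelled,
                "failed": c.failed,
            }
        )
    return pd.DataFrame(rows)
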