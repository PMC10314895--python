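"""Comparative degradomics hit calling.

The deconvolution logic of a PROTAC degradomics experiment: a protein is
a candidate direct target if it changes significantly under PROTAC
treatment (fold change > 1.5, Q < 0.05), does not change under either
control arm (the parent inhibitor, sharing the warhead's pharmacology,
and the free E3-ligase ligand, recruiting the same ligase), reproduces
with concordant direction across replicate experiments, and survives a
stringent down-regulation tier (log2 fold change < -1 and
-log10 Q > 2.5, i.e. Q < 10^-2.5).  All threshold comparisons are
strict, matching the printed "<" / ">" conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import quantio
from .diffstat import two_group_test

__all__ = [
    "HitThresholds",
    "HitSet",
    "call_arm_hits",
    "exclusive_hits",
    "intersect_replicates",
    "stringent_filter",
    "volcano_table",
    "deconvolution_funnel",
]


@dataclass(frozen=True)
class HitThresholds:
    """Significance cuts for tiered hit calling.

    fc_min is a linear fold change (the first-tier cut is
    |log2fc| > log2(fc_min)); stringent thresholds act on log2fc and
    -log10(q) directly and apply to down-regulated proteins only.
    """

    fc_min: float = 1.5
    q_max: float = 0.05
    stringent_log2fc_max: float = -1.0
    stringent_neglog10q_min: float = 2.5

    def __post_init__(self):
        if not self.fc_min > 1:
            raise ValueError("fc_min must be > 1")
        if not 0 < self.q_max < 1:
            raise ValueError("q_max must be in (0, 1)")
        if not (np.isfinite(self.stringent_log2fc_max)
                and np.isfinite(self.stringent_neglog10q_min)):
            raise ValueError("stringent thresholds must be finite")

    @property
    def log2fc_min(self) -> float:
        return float(np.log2(self.fc_min))

    @property
    def stringent_q_max(self) -> float:
        """The stringent -log10(q) cut expressed as a q threshold."""
        return float(10.0 ** (-self.stringent_neglog10q_min))


@dataclass
class HitSet:
    """Direction-annotated hit calls for one contrast.

    ``table`` is indexed by protein_id with columns ``log2fc``, ``q``,
    ``direction`` ("up"/"down") and ``tier`` ("primary"/"stringent").
    """

    contrast: str
    thresholds: HitThresholds
    table: pd.DataFrame

    @property
    def proteins(self) -> set:
        return set(self.table.index)

    def directions(self) -> pd.Series:
        return self.table["direction"]

    def __len__(self) -> int:
        return len(self.table)


def _empty_hit_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["log2fc", "q", "direction", "tier"],
        index=pd.Index([], name="protein_id"),
    )


def call_arm_hits(
    diff: pd.DataFrame,
    thresholds: HitThresholds = HitThresholds(),
    contrast: str = "",
    fc_required: bool = True,
) -> HitSet:
    """First-tier hits: |log2fc| > log2(fc_min) and q < q_max (strict).

    Untested proteins are excluded (their status survives in the
    DiffTable).  ``fc_required=False`` drops the fold-change floor,
    which is useful when screening control arms for *any* evidence of
    change rather than calling hits.
    """
    tested = diff[diff["status"] != "untested"]
    sig = tested["q"] < thresholds.q_max
    if fc_required:
        sig &= tested["log2fc"].abs() > thresholds.log2fc_min
    hits = tested.loc[sig, ["log2fc", "q"]].copy()
    hits["direction"] = np.where(hits["log2fc"] > 0, "up", "down")
    hits["tier"] = "primary"
    hits.index.name = "protein_id"
    return HitSet(contrast=contrast, thresholds=thresholds, table=hits)


def exclusive_hits(treatment_hits: HitSet, control_hitsets: Sequence[HitSet]) -> HitSet:
    """Treatment hits absent from every control hit set."""
    excluded = set()
    for ctrl in control_hitsets:
        excluded |= ctrl.proteins
    keep = [p for p in treatment_hits.table.index if p not in excluded]
    return HitSet(
        contrast=treatment_hits.contrast,
        thresholds=treatment_hits.thresholds,
        table=treatment_hits.table.loc[keep],
    )


def intersect_replicates(hits_a: HitSet, hits_b: HitSet) -> HitSet:
    """Proteins hit in both replicates with concordant direction.

    Direction-discordant proteins are excluded and recorded in the
    result's ``table.attrs["direction_mismatch"]``.
    """
    common = sorted(hits_a.proteins & hits_b.proteins)
    dir_a = hits_a.table["direction"]
    dir_b = hits_b.table["direction"]
    concordant = [p for p in common if dir_a[p] == dir_b[p]]
    mismatched = [p for p in common if dir_a[p] != dir_b[p]]
    table = hits_a.table.loc[concordant].copy()
    table.attrs["direction_mismatch"] = mismatched
    return HitSet(contrast=hits_a.contrast, thresholds=hits_a.thresholds, table=table)


def stringent_filter(
    diff: pd.DataFrame,
    shared: HitSet,
    thresholds: HitThresholds = HitThresholds(),
) -> HitSet:
    """Stringent tier: down-regulated shared hits with
    log2fc < stringent_log2fc_max and -log10(q) > stringent_neglog10q_min.

    ``diff`` supplies the statistics the stringent cuts act on (e.g. a
    pooled DiffTable over the shared-protein set).
    """
    keep = []
    for p in shared.table.index:
        if shared.table.at[p, "direction"] != "down" or p not in diff.index:
            continue
        lfc = diff.at[p, "log2fc"]
        q = diff.at[p, "q"]
        if not np.isfinite(lfc) or not np.isfinite(q):
            continue
        if lfc < thresholds.stringent_log2fc_max and q < thresholds.stringent_q_max:
            keep.append(p)
    table = diff.loc[keep, ["log2fc", "q"]].copy()
    table["direction"] = "down"
    table["tier"] = "stringent"
    table.index.name = "protein_id"
    return HitSet(contrast=shared.contrast, thresholds=thresholds, table=table)


def volcano_table(
    diff: pd.DataFrame,
    hitset: HitSet | None = None,
    neglog10q_cap: float = 300.0,
) -> pd.DataFrame:
    """Plotting coordinates (log2fc, -log10 q) with hit annotation.

    One row per tested protein; q = 0 is capped at ``neglog10q_cap``.
    """
    tested = diff[diff["status"] != "untested"]
    with np.errstate(divide="ignore"):
        nlq = -np.log10(tested["q"].to_numpy(dtype=float))
    nlq = np.minimum(nlq, neglog10q_cap)
    out = pd.DataFrame(
        {"log2fc": tested["log2fc"], "neglog10_q": nlq},
        index=tested.index,
    )
    out["tier"] = ""
    out["direction"] = ""
    if hitset is not None:
        idx = out.index.intersection(hitset.table.index)
        out.loc[idx, "tier"] = hitset.table.loc[idx, "tier"]
        out.loc[idx, "direction"] = hitset.table.loc[idx, "direction"]
    return out


def deconvolution_funnel(
    experiments: Sequence[tuple[pd.DataFrame, pd.DataFrame]],
    treatment_arm: str = "protac",
    reference_arm: str = "vehicle",
    control_arms: Sequence[str] = ("parent", "e3ligand"),
    thresholds: HitThresholds = HitThresholds(),
    control_q_max: float = 0.25,
    min_per_arm: int = 2,
    test: str = "student",
) -> dict:
    """End-to-end target deconvolution over replicate experiments.

    Per experiment: log2 transform, median normalization, minimum
    detection filter, treatment-vs-reference DiffTable, first-tier hit
    calls, and exclusion of proteins showing any evidence of change
    (q < ``control_q_max``, no fold-change floor) in a control arm.
    Exclusive hits are then intersected across experiments with
    direction concordance required.  The stringent tier is evaluated on
    a pooled DiffTable computed from the shared-protein set with the
    samples of all experiments combined, which uses the full replication
    for the final, high-confidence list.

    ``control_q_max`` deliberately sits above the treatment ``q_max``:
    when screening controls, sensitivity to any shared-pharmacology or
    ligase-ligand effect matters more than a calibrated error rate.
    Setting it equal to ``thresholds.q_max`` (and re-imposing the fold
    change floor via ``call_arm_hits``) reproduces the fully symmetric,
    more conservative variant.

    Returns a dict with per-experiment DiffTables and hit sets, the
    shared (replicate-intersected) hit set, the pooled DiffTable, and
    the stringent hit set.
    """
    prepared = []
    for quant, design in experiments:
        arms = [treatment_arm, reference_arm, *[a for a in control_arms
                                                if (design["arm"] == a).any()]]
        log2m = quantio.median_normalize(quantio.log2_transform(quant))
        filtered = quantio.filter_min_detection(log2m, design, min_per_arm, arms=arms)
        prepared.append((filtered, design, arms))

    per_experiment = []
    exclusive = []
    for i, (log2m, design, arms) in enumerate(prepared):
        diff = two_group_test(log2m, design, treatment_arm, reference_arm, test=test)
        treat_hits = call_arm_hits(diff, thresholds, contrast=f"exp{i}:{treatment_arm}")
        ctrl_sets = []
        ctrl_thresholds = HitThresholds(
            fc_min=thresholds.fc_min,
            q_max=control_q_max,
            stringent_log2fc_max=thresholds.stringent_log2fc_max,
            stringent_neglog10q_min=thresholds.stringent_neglog10q_min,
        )
        for arm in arms[2:]:
            cdiff = two_group_test(log2m, design, arm, reference_arm, test=test)
            ctrl_sets.append(
                call_arm_hits(cdiff, ctrl_thresholds,
                              contrast=f"exp{i}:{arm}", fc_required=False)
            )
        excl = exclusive_hits(treat_hits, ctrl_sets)
        per_experiment.append({"diff": diff, "hits": treat_hits,
                               "controls": ctrl_sets, "exclusive": excl})
        exclusive.append(excl)

    shared = exclusive[0]
    for other in exclusive[1:]:
        shared = intersect_replicates(shared, other)

    # pooled DiffTable over the shared-protein set, all experiments' samples
    common = set(prepared[0][0].index)
    for log2m, _, _ in prepared[1:]:
        common &= set(log2m.index)
    common = sorted(common)
    pooled_parts = []
    design_parts = []
    for i, (log2m, design, _) in enumerate(prepared):
        part = log2m.loc[common].copy()
        part.columns = [f"exp{i}__{c}" for c in part.columns]
        pooled_parts.append(part)
        d = design.copy()
        d["sample_id"] = [f"exp{i}__{s}" for s in d["sample_id"]]
        design_parts.append(d)
    pooled_matrix = pd.concat(pooled_parts, axis=1)
    pooled_design = pd.concat(design_parts, ignore_index=True)
    pooled_diff = two_group_test(
        pooled_matrix, pooled_design, treatment_arm, reference_arm, test=test
    )
    stringent = stringent_filter(pooled_diff, shared, thresholds)

    return {
        "per_experiment": per_experiment,
        "shared": shared,
        "pooled_diff": pooled_diff,
        "stringent": stringent,
    }
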