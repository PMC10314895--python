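"""Synthetic multi-arm degradomics experiments.

The generator emulates the design of a PROTAC target-deconvolution
study: a vehicle (DMSO) arm, a parent-inhibitor arm, a free E3-ligase
ligand arm, and the PROTAC arm, with ~5,000 quantified proteins and 4
replicates per arm, optionally as two replicate experiments whose
detected protein sets only partially overlap.

Planted protein classes encode the deconvolution logic:

* ``direct_target`` — degraded only by the PROTAC (the ternary-complex
  mechanism needs both warhead and ligase ligand in one molecule);
* ``shared_pharmacology`` — responds to the warhead's target engagement,
  so it moves with matched sign under both parent and PROTAC;
* ``neosubstrate`` — recruited by the ligase ligand itself, so it moves
  under both the free E3 ligand and the PROTAC;
* ``null`` — no planted effect anywhere.

Intensities are multiplicative log-normal around a per-protein baseline:
``2 ** (baseline + batch + effect + noise)`` with the log2 noise SD
derived from the linear coefficient of variation via
``sigma_ln = sqrt(ln(1 + CV^2))``.  The per-protein baseline is shared
across replicate experiments (abundance is a property of the protein);
each experiment adds an independent per-protein batch offset.
Missingness is detection-level: a protein is either quantified in an
experiment or absent from its matrix entirely, completely at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimProteomeConfig",
    "simulate_quant_experiment",
    "simulate_replicate_pair",
    "write_ground_truth",
]

CLASSES = ("direct_target", "shared_pharmacology", "neosubstrate", "null")

_DEFAULT_EFFECTS: Mapping[str, Mapping[str, float]] = {
    "direct_target": {"protac": -2.0},
    "shared_pharmacology": {"parent": -2.0, "protac": -2.0},
    "neosubstrate": {"e3ligand": -2.0, "protac": -2.0},
}


@dataclass(frozen=True)
class SimProteomeConfig:
    """Study-design parameters for the synthetic degradomics generator.

    Defaults mirror the emulated experiment: four arms including the
    free E3 ligand control, 4 replicates per arm, ~5,000 proteins, a
    linear CV of 0.2 on intensities, and effect sizes of -2 log2 units
    (4-fold depletion) for every planted class in its responsive arms.
    """

    n_proteins: int = 5000
    arms: tuple[str, ...] = ("vehicle", "parent", "e3ligand", "protac")
    reference_arm: str = "vehicle"
    n_replicates_per_arm: int = 4
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0
    noise_cv: float = 0.2
    batch_log2_sd: float = 0.25
    n_direct_targets: int = 6
    n_shared_pharmacology: int = 30
    n_neosubstrates: int = 10
    effect_log2: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_EFFECTS.items()}
    )
    detect_prob: float = 1.0
    always_detect_planted: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_planted > self.n_proteins:
            raise ValueError(
                f"planted class counts ({self.n_planted}) exceed n_proteins"
                f" ({self.n_proteins})"
            )
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0 <= self.detect_prob <= 1:
            raise ValueError("detect_prob must be in [0, 1]")
        if self.reference_arm not in self.arms:
            raise ValueError("reference_arm must be one of arms")
        if self.n_replicates_per_arm < 2:
            raise ValueError("need >= 2 replicates per arm")
        for cls, per_arm in self.effect_log2.items():
            if cls not in CLASSES:
                raise ValueError(f"unknown class {cls!r}")
            for arm in per_arm:
                if arm not in self.arms:
                    raise ValueError(f"effect for unknown arm {arm!r}")
        shared = self.effect_log2.get("shared_pharmacology", {})
        signs = {np.sign(v) for v in shared.values() if v != 0}
        if len(signs) > 1:
            raise ValueError("shared_pharmacology effects must have matched sign")
        direct = self.effect_log2.get("direct_target", {})
        bad = [a for a, v in direct.items()
               if v != 0 and a not in ("protac",)]
        if bad:
            raise ValueError("direct_target may only have an effect in the protac arm")

    @property
    def n_planted(self) -> int:
        return self.n_direct_targets + self.n_shared_pharmacology + self.n_neosubstrates

    @property
    def sigma_log2(self) -> float:
        """Log2-scale noise SD matching the configured linear CV."""
        return float(np.sqrt(np.log1p(self.noise_cv**2)) / np.log(2))


def _protein_ids(n: int) -> pd.Index:
    width = max(5, len(str(n)))
    return pd.Index([f"P{i:0{width}d}" for i in range(1, n + 1)], name="protein_id")


def _ground_truth(config: SimProteomeConfig) -> pd.DataFrame:
    """Per-protein class labels and planted log2 effects per arm."""
    ids = _protein_ids(config.n_proteins)
    classes = np.array(["null"] * config.n_proteins, dtype=object)
    k = 0
    for cls, count in [
        ("direct_target", config.n_direct_targets),
        ("shared_pharmacology", config.n_shared_pharmacology),
        ("neosubstrate", config.n_neosubstrates),
    ]:
        classes[k:k + count] = cls
        k += count
    truth = pd.DataFrame({"class": classes}, index=ids)
    for arm in config.arms:
        if arm == config.reference_arm:
            continue
        eff = np.zeros(config.n_proteins)
        for cls, per_arm in config.effect_log2.items():
            eff[classes == cls] = per_arm.get(arm, 0.0)
        truth[f"effect_{arm}"] = eff
    return truth


def _effect_matrix(config: SimProteomeConfig, truth: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        arm: (truth[f"effect_{arm}"].to_numpy()
              if arm != config.reference_arm else np.zeros(config.n_proteins))
        for arm in config.arms
    }


def _render_experiment(
    config: SimProteomeConfig,
    rng: np.random.Generator,
    baseline: np.ndarray,
    effects: dict[str, np.ndarray],
    detected: np.ndarray,
    batch: np.ndarray,
    experiment_id: str,
    sample_suffix: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    ids = _protein_ids(config.n_proteins)[detected]
    n_det = int(detected.sum())
    n_rep = config.n_replicates_per_arm
    sigma = config.sigma_log2
    columns, design_rows, blocks = [], [], []
    for arm in config.arms:
        mu = baseline[detected] + batch[detected] + effects[arm][detected]
        noise = (rng.normal(0.0, sigma, size=(n_det, n_rep))
                 if sigma > 0 else np.zeros((n_det, n_rep)))
        blocks.append(mu[:, None] + noise)
        for j in range(n_rep):
            sid = f"{arm}_r{j + 1}{sample_suffix}"
            columns.append(sid)
            design_rows.append({"sample_id": sid, "arm": arm,
                                "experiment_id": experiment_id})
    log2 = np.concatenate(blocks, axis=1)
    quant = pd.DataFrame(np.exp2(log2), index=ids, columns=columns)
    design = pd.DataFrame(design_rows)
    return quant, design


def simulate_quant_experiment(
    config: SimProteomeConfig = SimProteomeConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """One synthetic experiment: (quant matrix, design, ground truth).

    The quant matrix holds linear-scale intensities for the detected
    proteins; ground truth covers all proteins including undetected
    ones.
    """
    rng = np.random.default_rng(config.seed)
    truth = _ground_truth(config)
    effects = _effect_matrix(config, truth)
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                          config.n_proteins)
    detected = rng.random(config.n_proteins) < config.detect_prob
    if config.always_detect_planted:
        detected[: config.n_planted] = True
    quant, design = _render_experiment(
        config, rng, baseline, effects, detected,
        batch=np.zeros(config.n_proteins), experiment_id="exp1",
    )
    return quant, design, truth


def simulate_replicate_pair(
    config: SimProteomeConfig = SimProteomeConfig(),
    overlap_fraction: float = 0.725,
) -> tuple[
    tuple[pd.DataFrame, pd.DataFrame],
    tuple[pd.DataFrame, pd.DataFrame],
    pd.DataFrame,
]:
    """Two replicate experiments with partially overlapping detection.

    Null proteins are detected in each experiment independently with
    probability ``p = 2f / (1 + f)``, which makes the expected
    intersection / union ratio of the two detected sets equal to the
    requested ``overlap_fraction`` f.  Planted proteins are detected in
    both experiments when ``always_detect_planted`` is set (default), so
    recovery studies measure the method rather than detection luck.
    Baselines are shared between experiments; noise, batch offsets and
    detection are independent.
    """
    if not 0 < overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in (0, 1]")
    rng = np.random.default_rng(config.seed)
    truth = _ground_truth(config)
    effects = _effect_matrix(config, truth)
    n = config.n_proteins
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)
    p_det = 2 * overlap_fraction / (1 + overlap_fraction)
    det_a = rng.random(n) < p_det
    det_b = rng.random(n) < p_det
    if config.always_detect_planted:
        det_a[: config.n_planted] = True
        det_b[: config.n_planted] = True
    batch_a = rng.normal(0.0, config.batch_log2_sd, n) if config.batch_log2_sd > 0 else np.zeros(n)
    batch_b = rng.normal(0.0, config.batch_log2_sd, n) if config.batch_log2_sd > 0 else np.zeros(n)
    exp_a = _render_experiment(config, rng, baseline, effects, det_a, batch_a,
                               "expA", sample_suffix="_A")
    exp_b = _render_experiment(config, rng, baseline, effects, det_b, batch_b,
                               "expB", sample_suffix="_B")
    return exp_a, exp_b, truth


def write_ground_truth(truth: pd.DataFrame, path) -> None:
    """Ground-truth TSV: protein_id, class, and per-arm planted effects."""
    truth.to_csv(path, sep="\t")
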