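"""Synthetic dose-response tables from a known generative model."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["simulate_dose_response"]


def simulate_dose_response(
    model,
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Responses = model.predict(conc) + Gaussian noise.

    ``model`` is any object with a ``predict`` method over molar
    concentrations (e.g. :class:`~degradomap.assayfit.FourPLFit` or
    :class:`~degradomap.assayfit.BellFit`).  Returns a DataFrame with
    columns ``concentration_M``, ``response``, ``replicate``.
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        resp = np.asarray(model.predict(conc), dtype=float)
        if noise_sd > 0:
            resp = resp + rng.normal(0.0, noise_sd, size=conc.shape)
        rows.append(pd.DataFrame({
            "concentration_M": conc, "response": resp, "replicate": rep,
        }))
    return pd.concat(rows, ignore_index=True)
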