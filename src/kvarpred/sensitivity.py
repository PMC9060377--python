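"""Consistency-based input-sensitivity analysis of trained ensembles.

For each (input feature, output) pair, every member model of every ensemble
replicate is probed on every instance: the feature is nudged by a small delta
in standardized units and the sign of the output movement is recorded.  The
net consistency is (n_positive - n_negative) / n_total over all recorded
signs; exactly-zero responses count to neither side and shrink n_total, so a
half-up/half-down feature scores 0 and a strictly monotone one scores +-1.
Magnitudes of the movements are deliberately ignored — rescaling the inputs
makes them meaningless; only the direction is interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import PARAMETERS
from .features import FEATURE_SETS
from .network import TrainedEnsemble, forward

#: Zero-response tolerance: |movement| below this counts to neither side.
ZERO_RESPONSE_TOL = 1e-12


class SensitivityError(ValueError):
    """Ensembles with mismatched feature sets or invalid perturbation."""


@dataclass
class SensitivityReport:
    """Net consistency in [-1, 1] per (feature, output)."""

    feature_names: tuple[str, ...]
    consistency: np.ndarray     # (n_features, 4)
    n_models: int
    n_instances: int
    delta: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.consistency, index=list(self.feature_names), columns=list(PARAMETERS)
        )


def input_sensitivity(
    ensembles: list[TrainedEnsemble],
    X: np.ndarray,
    delta: float = 0.1,
) -> SensitivityReport:
    """Net consistency of output movement under a +delta feature perturbation.

    ``X`` is the raw feature matrix of the probing instances (typically the
    training set); each member model standardizes it with its own scaler and
    the perturbation is applied post-scaling, so ``delta`` is in standard
    deviations of the scaled feature (default 0.1).
    """
    if delta <= 0:
        raise SensitivityError("delta must be positive")
    if not ensembles:
        raise SensitivityError("need at least one ensemble")
    fset = ensembles[0].feature_set
    if any(e.feature_set != fset for e in ensembles):
        raise SensitivityError("all ensembles must share one feature set")
    names = FEATURE_SETS[fset]
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n_feat = len(names)
    pos = np.zeros((n_feat, 4))
    neg = np.zeros((n_feat, 4))
    zero = np.zeros((n_feat, 4))
    n_models = 0
    for ens in ensembles:
        for model in ens.models:
            n_models += 1
            Xs = model.scaler.transform(X) if model.scaler is not None else X
            base = forward(model, Xs)
            for f in range(n_feat):
                Xp = Xs.copy()
                Xp[:, f] += delta
                move = forward(model, Xp) - base
                pos[f] += (move > ZERO_RESPONSE_TOL).sum(axis=0)
                neg[f] += (move < -ZERO_RESPONSE_TOL).sum(axis=0)
                zero[f] += (np.abs(move) <= ZERO_RESPONSE_TOL).sum(axis=0)
    total = pos + neg
    with np.errstate(invalid="ignore"):
        consistency = np.where(total > 0, (pos - neg) / np.maximum(total, 1), 0.0)
    return SensitivityReport(
        feature_names=names,
        consistency=consistency,
        n_models=n_models,
        n_instances=X.shape[0],
        delta=delta,
    )
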