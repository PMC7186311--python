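"""Covariate-adjusted W-score normalization against the control group.

For each node j an ordinary least-squares model with age, gender and
education as predictors is fitted on control subjects only.  The W-score of
subject i at node j is then

    W_ij = (x_ij - e_ij) / s_res_j

where e_ij is the value expected under the control model for subject i's
covariates and s_res_j is the standard deviation of the control residuals.
W-scores therefore have mean 0 and standard deviation 1 in the control group,
and +/-1.645 mark the 95th/5th percentiles under Gaussian residuals.

The residual scale uses the sample-SD convention s_res_j = sqrt(RSS/(n-1)),
which makes the in-sample control SD exactly 1; the regression-sigma
convention sqrt(RSS/(n-p)) would not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import COVARIATE_COLUMNS, RegionalDataset
from .exceptions import DegenerateDataError, FitError, SchemaError

_PREDICTORS = ("intercept",) + COVARIATE_COLUMNS
_MIN_CONTROLS = 10


@dataclass
class WScoreModel:
    """Per-node control regression: coefficients and residual scale."""

    coef: pd.DataFrame          # nodes x (intercept, age, gender, education)
    s_res: pd.Series            # residual sample SD per node
    n_controls: int
    control_label: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coef.to_numpy())):
            raise FitError("non-finite regression coefficients")
        if (self.s_res <= 0).any():
            bad = self.s_res.index[self.s_res <= 0][0]
            raise DegenerateDataError(f"non-positive residual scale at node {bad!r}")

    @property
    def node_names(self) -> list[str]:
        return list(self.coef.index)

    def expected(self, covariates: pd.DataFrame) -> np.ndarray:
        """e_ij: model expectation for each subject at each node."""
        X = np.column_stack(
            [np.ones(len(covariates))]
            + [covariates[c].to_numpy(dtype=float) for c in COVARIATE_COLUMNS]
        )
        return X @ self.coef.to_numpy().T

    # --------------------------------------------------------------------- io
    def to_json(self, path: str | Path) -> None:
        payload = {
            "control_label": self.control_label,
            "n_controls": self.n_controls,
            "predictors": list(_PREDICTORS),
            "nodes": {
                node: {
                    "coef": [float(v) for v in self.coef.loc[node]],
                    "s_res": float(self.s_res[node]),
                }
                for node in self.coef.index
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "WScoreModel":
        payload = json.loads(Path(path).read_text())
        nodes = payload["nodes"]
        coef = pd.DataFrame(
            {node: rec["coef"] for node, rec in nodes.items()},
            index=list(_PREDICTORS),
        ).T
        s_res = pd.Series({node: rec["s_res"] for node, rec in nodes.items()})
        return cls(
            coef=coef,
            s_res=s_res,
            n_controls=int(payload["n_controls"]),
            control_label=payload["control_label"],
        )


def fit_wscore_model(dataset: RegionalDataset, control_label: str = "CN") -> WScoreModel:
    """OLS per node on control subjects; residual SD with n-1 denominator."""
    controls = dataset.subset(control_label)
    n = controls.n_subjects
    n_pred = len(_PREDICTORS)
    if n < _MIN_CONTROLS or n <= n_pred:
        raise FitError(
            f"{n} control subjects; need at least {max(_MIN_CONTROLS, n_pred + 1)}"
        )
    X = np.column_stack(
        [np.ones(n)] + [controls.covariates[c].to_numpy(dtype=float) for c in COVARIATE_COLUMNS]
    )
    Y = controls.values.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    residuals = Y - X @ beta
    rss = np.einsum("ij,ij->j", residuals, residuals)
    s_res = np.sqrt(rss / (n - 1))

    scale_floor = 1e-12 * max(1.0, float(np.abs(Y).max()))
    dead = np.nonzero(s_res <= scale_floor)[0]
    if dead.size:
        raise DegenerateDataError(
            f"zero residual variance in controls at node {controls.node_names[dead[0]]!r}"
        )
    return WScoreModel(
        coef=pd.DataFrame(beta.T, index=controls.node_names, columns=list(_PREDICTORS)),
        s_res=pd.Series(s_res, index=controls.node_names),
        n_controls=n,
        control_label=control_label,
    )


def apply_wscore(model: WScoreModel, dataset: RegionalDataset) -> RegionalDataset:
    """Replace every value by its W-score under the control-fitted model.

    Applied to ALL subjects: patients are normalized against the control model
    without refitting.
    """
    if model.node_names != dataset.node_names:
        raise SchemaError("model nodes do not match dataset nodes")
    expected = model.expected(dataset.covariates)
    w = (dataset.values.to_numpy(dtype=float) - expected) / model.s_res.to_numpy()
    return dataset.with_values(w)
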