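"""Applicability domain: scaffold whitelist + PCA bounding box.

A query compound is in-domain when (a) its Murcko scaffold belongs to the
training scaffold whitelist (if scaffold gating is enabled) and (b) its
projection onto the training PCA components lies inside the closed
per-component [min, max] box of the training scores (if box gating is
enabled). Boundaries are inclusive so every training compound is inside
its own box.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .eda import pca
from .scaffolds import murcko_scaffold


@dataclass
class ADModel:
    feature_names: list[str]
    feature_means: np.ndarray
    feature_stds: np.ndarray
    loadings: np.ndarray          # (n_components, n_features)
    box: list[tuple[float, float]]  # per-component closed intervals
    scaffold_whitelist: set[str] = field(default_factory=set)
    use_scaffold_gate: bool = True
    use_box_gate: bool = True

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def project(self, features: pd.DataFrame) -> np.ndarray:
        if list(features.columns) != self.feature_names:
            raise ValueError("query feature names do not match AD training features")
        z = (features.to_numpy(dtype=float) - self.feature_means) / self.feature_stds
        return z @ self.loadings.T

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "feature_names": self.feature_names,
                    "feature_means": self.feature_means.tolist(),
                    "feature_stds": self.feature_stds.tolist(),
                    "loadings": self.loadings.tolist(),
                    "box": [list(b) for b in self.box],
                    "scaffold_whitelist": sorted(self.scaffold_whitelist),
                    "use_scaffold_gate": self.use_scaffold_gate,
                    "use_box_gate": self.use_box_gate,
                },
                indent=2,
                sort_keys=True,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ADModel":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_names=d["feature_names"],
            feature_means=np.array(d["feature_means"]),
            feature_stds=np.array(d["feature_stds"]),
            loadings=np.array(d["loadings"]),
            box=[tuple(b) for b in d["box"]],
            scaffold_whitelist=set(d["scaffold_whitelist"]),
            use_scaffold_gate=d["use_scaffold_gate"],
            use_box_gate=d["use_box_gate"],
        )


def fit_ad(
    train_matrix: pd.DataFrame,
    scaffold_whitelist: set[str] | None = None,
    n_components: int = 2,
    use_scaffold_gate: bool = True,
    use_box_gate: bool = True,
) -> ADModel:
    """Fit the AD on standardized training features.

    PCA is fitted on the training matrix; the box is the [min, max] range of
    training scores on each retained component. An empty/None whitelist
    disables the scaffold gate.
    """
    if n_components < 1:
        raise ValueError("n_components must be at least 1")
    res = pca(train_matrix, n_components)
    scores = res.scores.to_numpy()
    box = [(float(scores[:, j].min()), float(scores[:, j].max())) for j in range(n_components)]
    whitelist = set(scaffold_whitelist or ())
    return ADModel(
        feature_names=list(res.loadings.columns),
        feature_means=res.feature_means.to_numpy(),
        feature_stds=res.feature_stds.to_numpy(),
        loadings=res.loadings.to_numpy(),
        box=box,
        scaffold_whitelist=whitelist,
        use_scaffold_gate=use_scaffold_gate and bool(whitelist),
        use_box_gate=use_box_gate,
    )


def in_domain(
    ad: ADModel, query_smiles: str, query_features: pd.DataFrame
) -> tuple[bool, list[str]]:
    """Decide admissibility of one query; returns (verdict, failed gates).

    Reasons list each failed gate: ``"scaffold"`` when the query's Murcko
    scaffold is not whitelisted, ``"box:PC_k"`` for every component whose
    score falls outside the training interval.
    """
    reasons: list[str] = []
    if ad.use_scaffold_gate:
        if murcko_scaffold(query_smiles) not in ad.scaffold_whitelist:
            reasons.append("scaffold")
    if ad.use_box_gate:
        score = ad.project(query_features)[0]
        for j, (lo, hi) in enumerate(ad.box):
            # closed interval with a float-noise guard so training extremes
            # remain in-domain regardless of projection arithmetic path
            tol = 1e-9 * max(1.0, abs(lo), abs(hi))
            if not (lo - tol <= score[j] <= hi + tol):
                reasons.append(f"box:PC_{j + 1}")
    return (not reasons), reasons
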