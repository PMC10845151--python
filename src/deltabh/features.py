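"""Feature-matrix assembly, Pearson-correlation pruning, importance subsets.

Four descriptor families are stacked per reaction in a fixed order —
``rdkit.`` (reaction-difference cheminformatics descriptors), ``topol.``
(TS-graph topological indices), ``bonds.`` (formed/broken bond counts) and
``pm7.`` (low-level electronic descriptors).  Highly collinear columns are
pruned with a greedy |Pearson r| filter, and a reduced descriptor set can
be derived from tree-ensemble gain importances.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bonds import bond_changes
from .molgraph import build_graph, weighted_adjacency
from .rdkit_desc import delta_descriptors
from .sqm import ReactionRecord, sqm_features
from .topo import topo_features

logger = logging.getLogger(__name__)

FAMILY_ORDER = ("rdkit", "topol", "bonds", "pm7")


@dataclass
class FeatureMatrix:
    """n_reactions x n_features descriptor table with family-tagged columns."""

    df: pd.DataFrame

    @property
    def names(self) -> list[str]:
        return list(self.df.columns)

    @property
    def families(self) -> list[str]:
        return [c.split(".", 1)[0] for c in self.df.columns]

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    def select(self, names: list[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.df[list(names)])

    def to_csv(self, path: str | Path) -> None:
        """CSV of the matrix plus a sidecar JSON of names and families."""
        path = Path(path)
        self.df.to_csv(path, index=False)
        sidecar = {"names": self.names, "families": self.families}
        path.with_suffix(".names.json").write_text(json.dumps(sidecar))


@dataclass
class ReducedSet:
    selected: list[str]
    importances: dict[str, float]


def _record_features(
    record: ReactionRecord, families: tuple[str, ...], n_bo_eigs: int
) -> dict[str, float]:
    row: dict[str, float] = {}
    if "rdkit" in families:
        dset = delta_descriptors(record.smiles_reactant, record.smiles_product)
        for name, val in zip(dset.names, dset.values):
            row[f"rdkit.{name}"] = float(val)
    if "topol" in families:
        g_ts = build_graph(record.geom_ts)
        weighted = weighted_adjacency(record.geom_ts, g_ts)
        for name, val in topo_features(g_ts, weighted).items():
            row[f"topol.{name}"] = float(val)
    if "bonds" in families:
        g_r = build_graph(record.geom_reactant)
        g_p = build_graph(record.geom_product)
        for name, val in bond_changes(g_r, g_p).items():
            row[f"bonds.{name}"] = float(val)
    if "pm7" in families:
        for name, val in sqm_features(record, n_bo_eigs=n_bo_eigs).items():
            row[f"pm7.{name}"] = float(val)
    return row


def assemble(
    records: list[ReactionRecord],
    families: tuple[str, ...] = FAMILY_ORDER,
    n_bo_eigs: int = 10,
    drop_constant: bool = True,
) -> FeatureMatrix:
    """Stack the descriptor families for a curated record list.

    Zero-variance columns are dropped (with a log line); any non-finite
    entry raises, naming the offending record and column.
    """
    families = tuple(f for f in FAMILY_ORDER if f in families)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # negative-BH warnings are per-record noise
        rows = [_record_features(r, families, n_bo_eigs) for r in records]
    df = pd.DataFrame(rows)
    bad = ~np.isfinite(df.to_numpy())
    if bad.any():
        i, j = np.argwhere(bad)[0]
        rid = records[i].record_id or f"index {i}"
        raise ValueError(f"non-finite feature {df.columns[j]!r} in record {rid}")
    if drop_constant:
        variances = df.var(axis=0, ddof=0)
        constant = list(df.columns[variances == 0.0])
        if constant:
            logger.info("dropping %d zero-variance columns: %s", len(constant), constant)
            df = df.drop(columns=constant)
    return FeatureMatrix(df)


def targets(records: list[ReactionRecord]) -> pd.DataFrame:
    """Regression targets: the barrier correction delta and the reaction energy."""
    return pd.DataFrame(
        {
            "delta": [r.target for r in records],
            "de_r": [r.product.energy - r.reactant.energy for r in records],
            "bh_pm7": [r.bh_pm7 for r in records],
            "bh_dft": [r.bh_dft for r in records],
        }
    )


def correlation_filter(
    m: FeatureMatrix,
    threshold: float = 0.9,
    reference_rows: np.ndarray | None = None,
) -> FeatureMatrix:
    """Greedy collinearity pruning at |Pearson r| > threshold.

    Columns are scanned in order; a column is dropped iff its absolute
    Pearson correlation with any already-retained column exceeds the
    threshold, so the earliest column of a correlated group survives.
    ``reference_rows`` restricts the correlation estimate to the training
    split while the selection applies to the full matrix (no leakage).
    """
    x = m.values if reference_rows is None else m.values[reference_rows]
    if x.shape[0] < 3:
        raise ValueError("need at least 3 rows to estimate correlations")
    with np.errstate(invalid="ignore"):
        corr = np.abs(np.corrcoef(x, rowvar=False))
    corr = np.nan_to_num(corr, nan=0.0)
    keep: list[int] = []
    for j in range(x.shape[1]):
        if all(corr[j, i] <= threshold for i in keep):
            keep.append(j)
    return FeatureMatrix(m.df.iloc[:, keep])


def importance_subset(model, m: FeatureMatrix, k: int = 49) -> ReducedSet:
    """Top-k features by tree-ensemble gain importance (ties by column order)."""
    gains = model.gain_importances()
    if k > len(m.names):
        warnings.warn(
            f"k={k} exceeds {len(m.names)} features; capped", stacklevel=2
        )
        k = len(m.names)
    order = {name: i for i, name in enumerate(m.names)}
    ranked = sorted(
        m.names, key=lambda name: (-gains.get(name, 0.0), order[name])
    )
    selected = ranked[:k]
    return ReducedSet(
        selected=selected,
        importances={name: gains.get(name, 0.0) for name in selected},
    )
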