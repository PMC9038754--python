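"""In-memory containers shared across the pipeline.

Tables (behavior, cohort metadata) are pandas DataFrames; the per-cohort
FC collection stores vectorized edges in one dense array because every
downstream consumer (kernels, Haufe features, aggregate-FC transfer)
works on edge vectors, not square matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import FCMatrix, devectorize_fc, fisher_average, n_edges

META_COLUMNS = [
    "participant",
    "site",
    "mean_fd",
    "mean_dvars",
    "age",
    "sex",
    "race_bin",
    "income_bin",
]


@dataclass
class ConnectomeSet:
    """Per-participant, per-state collection of vectorized FC matrices.

    Attributes
    ----------
    participants : list of str
    states : list of str
    edges : (n_participants, n_states, n_edges) array
        Strict-lower-triangle edge vectors (see :mod:`connpredict.connectome`).
    n_regions : int
    """

    participants: list
    states: list
    edges: np.ndarray
    n_regions: int

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        expect = (len(self.participants), len(self.states), n_edges(self.n_regions))
        if self.edges.shape != expect:
            raise ValueError(f"edges shape {self.edges.shape} != {expect}")
        self._pindex = {p: i for i, p in enumerate(self.participants)}
        if len(self._pindex) != len(self.participants):
            raise ValueError("duplicate participant ids")

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def state_edges(self, state: str) -> np.ndarray:
        """(n_participants, n_edges) edge matrix for one state."""
        return self.edges[:, self.states.index(state), :]

    def mean_state_edges(self) -> np.ndarray:
        """Fisher-z mean across states per participant ("Mean FC")."""
        return fisher_average(np.swapaxes(self.edges, 0, 1), axis=0)

    def matrix(self, participant: str, state: str) -> FCMatrix:
        vec = self.edges[self._pindex[participant], self.states.index(state)]
        return FCMatrix(values=devectorize_fc(vec, self.n_regions), state=state)

    def subset(self, participant_ids) -> "ConnectomeSet":
        rows = [self._pindex[p] for p in participant_ids]
        return ConnectomeSet(
            participants=list(participant_ids),
            states=list(self.states),
            edges=self.edges[rows],
            n_regions=self.n_regions,
        )


@dataclass
class BehaviorTable:
    """Behavioral measures (participants x measures) plus a measure->domain map."""

    values: pd.DataFrame
    domains: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [m for m in self.values.columns if m not in self.domains]
        if missing:
            raise ValueError(f"measures without a domain: {missing}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate participant ids in behavior table")

    @property
    def measures(self) -> list:
        return list(self.values.columns)

    @property
    def participants(self) -> list:
        return list(self.values.index)

    def domain_of(self, measure: str) -> str:
        return self.domains[measure]

    def measures_in(self, domain: str) -> list:
        return [m for m in self.values.columns if self.domains[m] == domain]

    def y(self, measure: str, participant_ids=None) -> np.ndarray:
        col = self.values[measure]
        if participant_ids is not None:
            col = col.loc[list(participant_ids)]
        return col.to_numpy(dtype=float)


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Check the cohort table has the expected columns and unique ids."""
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if meta["participant"].duplicated().any():
        dup = meta.loc[meta["participant"].duplicated(), "participant"].tolist()
        raise ValueError(f"duplicate participant ids: {dup}")
    if "site_cluster" in meta.columns:
        clusters = np.sort(meta["site_cluster"].unique())
        if not np.array_equal(clusters, np.arange(len(clusters))):
            raise ValueError("site_cluster indices must be contiguous from 0")
    return meta


def align_cohort(
    connectomes: ConnectomeSet, behavior: BehaviorTable, meta: pd.DataFrame
):
    """Intersect the three sources by participant id (never by row order),
    dropping participants with any missing behavioral measure."""
    complete = behavior.values.dropna(axis=0)
    ids = [
        p
        for p in connectomes.participants
        if p in complete.index and p in set(meta["participant"])
    ]
    n_dropped = len(behavior.values) - len(complete)
    behavior2 = BehaviorTable(values=complete.loc[ids], domains=dict(behavior.domains))
    meta2 = (
        meta.set_index("participant").loc[ids].reset_index()
    )
    return connectomes.subset(ids), behavior2, meta2, n_dropped
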