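"""Readers, writers, the stratified-matching utility, and run manifests.

Interchange formats are plain text: CSV for tables, delimited square
matrices for FC (one file per participant and state) with a JSON
manifest recording region order, states, and the edge-vector convention.
Alignment across files is always by participant id, never by row order.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import FCMatrix, NetworkLabeling, vectorize_fc
from .containers import BehaviorTable, ConnectomeSet, validate_meta

__all__ = [
    "read_behavior_table",
    "write_behavior_table",
    "read_meta",
    "write_meta",
    "read_labels",
    "read_fc",
    "write_fc",
    "write_cohort",
    "read_cohort",
    "match_subsample",
    "RunManifest",
]


def read_behavior_table(path, domain_map_path=None) -> BehaviorTable:
    """Read a participant x measure CSV (and a measure,domain map CSV).

    Participants with any missing measure are dropped (their count is
    recorded on the returned table as ``n_dropped``).
    """
    df = pd.read_csv(path, index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate participant ids: {dup}")
    n0 = len(df)
    df = df.dropna(axis=0)
    if domain_map_path is not None:
        dm = pd.read_csv(domain_map_path)
        domains = dict(zip(dm.iloc[:, 0].astype(str), dm.iloc[:, 1].astype(str)))
    else:
        domains = {m: "unknown" for m in df.columns}
    table = BehaviorTable(values=df, domains={m: domains[m] for m in df.columns})
    table.n_dropped = n0 - len(df)  # type: ignore[attr-defined]
    return table


def write_behavior_table(table: BehaviorTable, path, domain_map_path=None) -> None:
    table.values.to_csv(path)
    if domain_map_path is not None:
        pd.DataFrame(
            {"measure": list(table.domains), "domain": list(table.domains.values())}
        ).to_csv(domain_map_path, index=False)


def read_meta(path) -> pd.DataFrame:
    return validate_meta(pd.read_csv(path))


def write_meta(meta: pd.DataFrame, path) -> None:
    validate_meta(meta).to_csv(path, index=False)


def read_labels(path) -> NetworkLabeling:
    return NetworkLabeling.from_csv(path)


def write_fc(fc: FCMatrix, path, region_names=None) -> None:
    names = region_names or [f"region_{i:03d}" for i in range(fc.n_regions)]
    pd.DataFrame(fc.values, index=names, columns=names).to_csv(path)


def read_fc(path, state: str = "") -> FCMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("FC matrix row and column region names disagree")
    return FCMatrix(values=df.to_numpy(dtype=float), state=state)


def write_cohort(outdir, connectomes: ConnectomeSet, behavior: BehaviorTable,
                 meta: pd.DataFrame, truth=None) -> None:
    """Write a cohort as one FC file per participant x state, behavior and
    meta CSVs, a domain map, and an optional ground-truth JSON sidecar."""
    out = Path(outdir)
    (out / "fc").mkdir(parents=True, exist_ok=True)
    for p in connectomes.participants:
        for s in connectomes.states:
            safe = s.replace("/", "_")
            write_fc(connectomes.matrix(p, s), out / "fc" / f"{p}_{safe}.csv")
    write_behavior_table(behavior, out / "behavior.csv", out / "domain_map.csv")
    write_meta(meta, out / "meta.csv")
    manifest = {
        "states": list(connectomes.states),
        "n_regions": connectomes.n_regions,
        "participants": list(connectomes.participants),
        "edge_order": "strict lower triangle, row-major",
    }
    (out / "cohort.json").write_text(json.dumps(manifest, indent=1))
    if truth is not None:
        truth.to_json(out / "truth.json")


def read_cohort(outdir):
    """Inverse of :func:`write_cohort` (truth sidecar not required)."""
    out = Path(outdir)
    manifest = json.loads((out / "cohort.json").read_text())
    states = manifest["states"]
    participants = manifest["participants"]
    n_regions = manifest["n_regions"]
    edges = np.empty(
        (len(participants), len(states), n_regions * (n_regions - 1) // 2)
    )
    for i, p in enumerate(participants):
        for j, s in enumerate(states):
            fc = read_fc(out / "fc" / f"{p}_{s.replace('/', '_')}.csv", state=s)
            edges[i, j] = vectorize_fc(fc)
    connectomes = ConnectomeSet(
        participants=participants, states=states, edges=edges, n_regions=n_regions
    )
    behavior = read_behavior_table(out / "behavior.csv", out / "domain_map.csv")
    meta = read_meta(out / "meta.csv")
    return connectomes, behavior, meta


def match_subsample(
    meta: pd.DataFrame,
    reference_marginals: dict,
    bin_columns: list,
    target_n: int,
    seed: int = 0,
):
    """Stratified subsampling matched to reference joint-bin proportions.

    Joint bins are the Cartesian product of the configured per-variable
    bins. For each joint bin with reference proportion ``pct``, draw
    ``round(pct * target_n)`` participants without replacement; if any
    bin demands more than it holds, fail with a structured shortfall
    report. Reference bins absent from the sample with zero target are
    skipped.

    Parameters
    ----------
    reference_marginals : dict mapping joint-bin key (tuple) -> proportion.
    bin_columns : meta columns whose values form the joint-bin key.

    Returns a list of selected participant ids.
    """
    rng = np.random.default_rng(seed)
    keys = list(zip(*(meta[c].astype(str) for c in bin_columns)))
    by_bin: dict = {}
    for pid, key in zip(meta["participant"], keys):
        by_bin.setdefault(key, []).append(pid)

    demands = {}
    shortfall = {}
    for key, pct in reference_marginals.items():
        want = int(round(pct * target_n))
        if want == 0:
            continue
        have = len(by_bin.get(tuple(key), []))
        if want > have:
            shortfall[tuple(key)] = {"wanted": want, "available": have}
        demands[tuple(key)] = want
    if shortfall:
        raise ValueError(
            f"matching infeasible at target_n={target_n}; shortfall per bin: {shortfall}"
        )
    selected = []
    for key, want in sorted(demands.items()):
        pool = by_bin[key]
        pick = rng.choice(len(pool), size=want, replace=False)
        selected.extend(pool[i] for i in sorted(pick))
    return selected


def sample_marginals(meta: pd.DataFrame, bin_columns: list) -> dict:
    """Joint-bin proportions of a cohort table (reference construction)."""
    keys = list(zip(*(meta[c].astype(str) for c in bin_columns)))
    counts = pd.Series(keys).value_counts()
    return {k: v / len(meta) for k, v in counts.items()}


class RunManifest:
    """Config snapshot, seeds, input digests and stage timings for a run."""

    def __init__(self, config: dict, seed: int) -> None:
        self.data = {
            "config": config,
            "seed": seed,
            "stages": {},
            "inputs": {},
        }
        self._t0 = {}

    def digest(self, name: str, path) -> None:
        h = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.data["inputs"][name] = {"path": str(path), "sha256": h}

    def start(self, stage: str) -> None:
        self._t0[stage] = time.time()

    def finish(self, stage: str, **info) -> None:
        entry = {"seconds": round(time.time() - self._t0.pop(stage, time.time()), 3)}
        entry.update(info)
        self.data["stages"][stage] = entry

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.data, indent=1, default=str))
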