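"""Response-dataset assembly and convex-hull pseudoabsence strategies.

Five model-ready datasets are built from a lake table: presence-absence
(surveyed lakes only), three presence-only variants whose pseudoabsences
are drawn from unsurveyed lakes (randomly; outside the convex hull of
presence coordinates — "distant"; inside it — "proximal"), and an
abundance dataset labelled with frequency of occurrence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point

from .landscape import RESPONSE_COLUMNS

log = logging.getLogger(__name__)

KINDS = ("PA", "PO_random", "PO_distant", "PO_proximal", "ABUNDANCE")
OCCURRENCE_KINDS = ("PA", "PO_random", "PO_distant", "PO_proximal")
STRATEGIES = ("random", "distant", "proximal")


class DegenerateHullError(ValueError):
    """Fewer than 3 non-collinear presences: no planar hull exists."""


class InsufficientCandidatesError(RuntimeError):
    """A pseudoabsence strategy's candidate cell is smaller than n_pseudo."""


def covariate_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in RESPONSE_COLUMNS + ["true_suitability"]]


@dataclass
class ResponseDataset:
    """One model-ready dataset.

    ``df`` has columns id, x, y, role (presence / absence / pseudoabsence),
    label (0/1 for occurrence kinds, freq_occ for ABUNDANCE) and the
    covariates; an ``autocov`` column may be attached later.
    """

    kind: str
    df: pd.DataFrame
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown dataset kind {self.kind!r}")
        if not self.feature_names:
            self.feature_names = [
                c for c in self.df.columns if c not in ("id", "x", "y", "role", "label")
            ]
        if self.df["id"].duplicated().any():
            raise ValueError("a lake appears twice in the dataset")

    @property
    def features(self) -> pd.DataFrame:
        return self.df[self.feature_names]

    @property
    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy(dtype=float)

    @property
    def coords(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy(dtype=float)

    @property
    def is_occurrence(self) -> bool:
        return self.kind in OCCURRENCE_KINDS

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, kind: str) -> "ResponseDataset":
        return cls(kind=kind, df=pd.read_csv(path))


@dataclass
class HullPartition:
    """Convex hull of presence coordinates and the induced candidate split."""

    hull: object  # shapely Polygon
    inside_ids: list[str]
    outside_ids: list[str]

    @property
    def wkt(self) -> str:
        return self.hull.wkt


def presence_hull(table: pd.DataFrame) -> HullPartition:
    """Convex hull of presence lakes; partition unsurveyed candidates.

    Boundary points count as inside (proximal). Raises DegenerateHullError
    when presences are fewer than 3 or collinear.
    """
    pres = table[(table["surveyed"].astype(bool)) & (table["presence"] == 1)]
    if len(pres) < 3:
        raise DegenerateHullError(f"need >= 3 presences, got {len(pres)}")
    hull = MultiPoint(list(zip(pres["x"], pres["y"]))).convex_hull
    if hull.geom_type != "Polygon":
        raise DegenerateHullError("presence coordinates are collinear; hull is degenerate")
    cand = table[~table["surveyed"].astype(bool)]
    inside, outside = [], []
    for lake_id, x, y in zip(cand["id"], cand["x"], cand["y"]):
        (inside if hull.covers(Point(x, y)) else outside).append(lake_id)
    return HullPartition(hull=hull, inside_ids=inside, outside_ids=outside)


def _complete_cases(table: pd.DataFrame) -> pd.DataFrame:
    covs = covariate_columns(table)
    ok = table[covs].notna().all(axis=1) & np.isfinite(
        table[covs].to_numpy(dtype=float)
    ).all(axis=1)
    dropped = int((~ok).sum())
    if dropped:
        log.info("dropped %d lake(s) with incomplete covariates", dropped)
    return table[ok]


def draw_pseudoabsences(
    table: pd.DataFrame,
    strategy: str,
    n_pseudo: int | None = None,
    rng: np.random.Generator | None = None,
) -> ResponseDataset:
    """Presence-only dataset under one pseudoabsence selection strategy.

    Pseudoabsences are a uniform draw without replacement from unsurveyed
    lakes: all of them (random), those outside the presence convex hull
    (distant), or those inside it (proximal). Presences are labelled 1,
    pseudoabsences 0; surveyed true absences are excluded (replaced, not
    augmented). n_pseudo defaults to the number of surveyed absences.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    rng = rng or np.random.default_rng()
    table = _complete_cases(table)
    surveyed = table["surveyed"].astype(bool)
    pres = table[surveyed & (table["presence"] == 1)]
    if n_pseudo is None:
        n_pseudo = int((surveyed & (table["presence"] == 0)).sum())
    if strategy == "random":
        pool = table.loc[~surveyed, "id"].tolist()
    else:
        part = presence_hull(table)
        pool = part.outside_ids if strategy == "distant" else part.inside_ids
    if len(pool) < n_pseudo:
        raise InsufficientCandidatesError(
            f"strategy {strategy!r}: candidate pool holds {len(pool)} unsurveyed "
            f"lakes but {n_pseudo} pseudoabsences were requested "
            f"(shortfall {n_pseudo - len(pool)}); no top-up from other cells"
        )
    chosen = rng.choice(np.asarray(pool, dtype=object), size=n_pseudo, replace=False)
    pa = table[table["id"].isin(chosen)]
    covs = covariate_columns(table)
    rows = []
    for sub, role, label in ((pres, "presence", 1.0), (pa, "pseudoabsence", 0.0)):
        part_df = sub[["id", "x", "y"] + covs].copy()
        part_df.insert(3, "role", role)
        part_df.insert(4, "label", label)
        rows.append(part_df)
    kind = {"random": "PO_random", "distant": "PO_distant", "proximal": "PO_proximal"}
    return ResponseDataset(kind=kind[strategy], df=pd.concat(rows, ignore_index=True))


def build_dataset(
    table: pd.DataFrame,
    kind: str,
    n_pseudo: int | None = None,
    rng: np.random.Generator | None = None,
) -> ResponseDataset:
    """Assemble one of the five model-ready datasets.

    Lakes with any missing covariate are dropped (complete-case rule) with
    a logged count. PA and ABUNDANCE use surveyed lakes only; PO kinds
    delegate to :func:`draw_pseudoabsences`.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown dataset kind {kind!r}")
    if kind in ("PO_random", "PO_distant", "PO_proximal"):
        strategy = {"PO_random": "random", "PO_distant": "distant", "PO_proximal": "proximal"}
        return draw_pseudoabsences(table, strategy[kind], n_pseudo=n_pseudo, rng=rng)
    table = _complete_cases(table)
    sub = table[table["surveyed"].astype(bool)].copy()
    if sub.empty:
        raise ValueError(f"dataset {kind!r} is empty after filtering")
    covs = covariate_columns(table)
    df = sub[["id", "x", "y"] + covs].copy()
    df.insert(3, "role", np.where(sub["presence"] == 1, "presence", "absence"))
    label = sub["presence"] if kind == "PA" else sub["freq_occ"]
    df.insert(4, "label", label.to_numpy(dtype=float))
    return ResponseDataset(kind=kind, df=df.reset_index(drop=True))
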