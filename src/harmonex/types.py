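"""Core data containers shared by the simulation, equating, IRT and ML layers.

The package links two polytomous questionnaires answered by the same
respondents (a single-group, common-persons design): a short *source* scale
(5 items, sum range 0-10) and a longer *target* scale (11 items, sum range
0-22).  Items are scored 0/1/2, so each item carries one discrimination and
two threshold parameters under the generalized partial credit model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ItemParameters",
    "ScaleDefinition",
    "LatentSpec",
    "ResponseDataset",
    "save_item_banks",
    "load_item_banks",
]


@dataclass(frozen=True)
class ItemParameters:
    """GPCM parameters of a single polytomous item.

    Parameters
    ----------
    item_id
        Label used in data files and fitted-parameter exports.
    discrimination
        Slope ``a > 0``; the strength of the item/trait relationship.
    thresholds
        ``K - 1`` adjacent-category boundaries ``b_k`` on the latent scale:
        the trait value at which categories ``k-1`` and ``k`` are equally
        probable.
    """

    item_id: str
    discrimination: float
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        if not np.isfinite(self.discrimination) or self.discrimination <= 0:
            raise ValueError(
                f"item {self.item_id!r}: discrimination must be a positive "
                f"finite number, got {self.discrimination}"
            )
        b = tuple(float(x) for x in self.thresholds)
        if len(b) < 1 or not all(np.isfinite(b)):
            raise ValueError(f"item {self.item_id!r}: thresholds must be finite, got {b}")
        object.__setattr__(self, "thresholds", b)

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1

    def to_dict(self) -> dict:
        return {
            "item_id": self.item_id,
            "a": float(self.discrimination),
            "b": [float(x) for x in self.thresholds],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ItemParameters":
        return cls(item_id=d["item_id"], discrimination=d["a"], thresholds=tuple(d["b"]))


@dataclass(frozen=True)
class ScaleDefinition:
    """An item bank with a fixed number of response categories per item."""

    name: str
    items: tuple[ItemParameters, ...]
    n_categories: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        for it in self.items:
            if it.n_categories != self.n_categories:
                raise ValueError(
                    f"scale {self.name!r}: item {it.item_id!r} has "
                    f"{it.n_categories} categories, expected {self.n_categories}"
                )

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def sum_range(self) -> tuple[int, int]:
        """Inclusive range of the unweighted sum score."""
        return (0, self.n_items * (self.n_categories - 1))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_categories": self.n_categories,
            "items": [it.to_dict() for it in self.items],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScaleDefinition":
        return cls(
            name=d["name"],
            items=tuple(ItemParameters.from_dict(x) for x in d["items"]),
            n_categories=d.get("n_categories", 3),
        )


@dataclass(frozen=True)
class LatentSpec:
    """Latent trait layout of the generative model.

    One standard-normal trait (``n_traits=1``) gives the unidimensional
    case in which both scales measure exactly the same construct.  Two
    traits with correlation ``trait_correlation`` model partial construct
    overlap: the source items load on trait 1 and the target items on
    trait 2.  ``trait_correlation=1`` with two traits reproduces the
    unidimensional case.
    """

    n_traits: int = 1
    trait_correlation: float = 1.0

    def __post_init__(self) -> None:
        if self.n_traits not in (1, 2):
            raise ValueError(f"n_traits must be 1 or 2, got {self.n_traits}")
        if not -1.0 <= self.trait_correlation <= 1.0:
            raise ValueError(
                f"trait_correlation must lie in [-1, 1], got {self.trait_correlation}"
            )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw an ``n x 2`` matrix of (source trait, target trait) values."""
        if self.n_traits == 1:
            theta = rng.standard_normal(n)
            return np.column_stack([theta, theta])
        rho = self.trait_correlation
        z = rng.standard_normal((n, 2))
        # explicit Cholesky factor keeps |rho| = 1 exact
        t2 = rho * z[:, 0] + np.sqrt(max(1.0 - rho * rho, 0.0)) * z[:, 1]
        return np.column_stack([z[:, 0], t2])


@dataclass
class ResponseDataset:
    """Paired item responses of the same persons on both scales.

    Complete cases only: no missing entries, and both matrices share the
    person (row) order, as required by the single-group linking design.
    """

    source_responses: np.ndarray  # n x n_source_items, ints in {0..K-1}
    target_responses: np.ndarray  # n x n_target_items, ints in {0..K-1}
    person_ids: np.ndarray | None = None
    true_traits: np.ndarray | None = None  # n x 2, simulation truth
    source_scale: ScaleDefinition | None = None
    target_scale: ScaleDefinition | None = None

    def __post_init__(self) -> None:
        src = np.asarray(self.source_responses, dtype=int)
        tgt = np.asarray(self.target_responses, dtype=int)
        if src.ndim != 2 or tgt.ndim != 2:
            raise ValueError("response matrices must be two-dimensional")
        if src.shape[0] != tgt.shape[0]:
            raise ValueError(
                f"source and target must cover the same persons: "
                f"{src.shape[0]} vs {tgt.shape[0]} rows"
            )
        self.source_responses = src
        self.target_responses = tgt
        if self.person_ids is None:
            self.person_ids = np.arange(1, src.shape[0] + 1)
        else:
            self.person_ids = np.asarray(self.person_ids)
            if self.person_ids.shape[0] != src.shape[0]:
                raise ValueError("person_ids length does not match response rows")

    @property
    def n_persons(self) -> int:
        return self.source_responses.shape[0]

    @property
    def source_sums(self) -> np.ndarray:
        return self.source_responses.sum(axis=1)

    @property
    def target_sums(self) -> np.ndarray:
        return self.target_responses.sum(axis=1)

    def subset(self, idx: Sequence[int] | np.ndarray) -> "ResponseDataset":
        idx = np.asarray(idx)
        return ResponseDataset(
            source_responses=self.source_responses[idx],
            target_responses=self.target_responses[idx],
            person_ids=self.person_ids[idx],
            true_traits=None if self.true_traits is None else self.true_traits[idx],
            source_scale=self.source_scale,
            target_scale=self.target_scale,
        )

    def to_frame(self, include_traits: bool = False) -> pd.DataFrame:
        cols = {"person_id": self.person_ids}
        for j in range(self.source_responses.shape[1]):
            cols[f"src_{j + 1}"] = self.source_responses[:, j]
        for j in range(self.target_responses.shape[1]):
            cols[f"tgt_{j + 1}"] = self.target_responses[:, j]
        if include_traits and self.true_traits is not None:
            cols["theta_source"] = self.true_traits[:, 0]
            cols["theta_target"] = self.true_traits[:, 1]
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path, include_traits: bool = False) -> None:
        self.to_frame(include_traits=include_traits).to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ResponseDataset":
        src_cols = sorted(
            (c for c in df.columns if c.startswith("src_")), key=lambda c: int(c[4:])
        )
        tgt_cols = sorted(
            (c for c in df.columns if c.startswith("tgt_")), key=lambda c: int(c[4:])
        )
        if not src_cols or not tgt_cols:
            raise ValueError("expected src_* and tgt_* response columns")
        if df[src_cols + tgt_cols].isna().any().any():
            raise ValueError("missing responses: the pipeline expects complete cases")
        traits = None
        if {"theta_source", "theta_target"} <= set(df.columns):
            traits = df[["theta_source", "theta_target"]].to_numpy(dtype=float)
        return cls(
            source_responses=df[src_cols].to_numpy(dtype=int),
            target_responses=df[tgt_cols].to_numpy(dtype=int),
            person_ids=df["person_id"].to_numpy() if "person_id" in df else None,
            true_traits=traits,
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ResponseDataset":
        return cls.from_frame(pd.read_csv(path))


def save_item_banks(path: str | Path, **banks: ScaleDefinition) -> None:
    """Serialize one or more item banks to a single JSON document.

    The same schema is used for generator fixtures and for fitted GPCM
    parameters, so either can be loaded back with :func:`load_item_banks`.
    """
    payload = {name: bank.to_dict() for name, bank in banks.items()}
    Path(path).write_text(json.dumps(payload, indent=2))


def load_item_banks(path: str | Path) -> dict[str, ScaleDefinition]:
    payload = json.loads(Path(path).read_text())
    return {name: ScaleDefinition.from_dict(d) for name, d in payload.items()}
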