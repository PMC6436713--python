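"""Patient-level ordinal dataset with facility/county nesting.

The analysis dataframe has one row per patient: an ordinal outcome coded
1..K (1 = no contraceptive method, 2 = less-effective method, 3 = highly
effective method for the K=3 study design), dummy-expanded covariate
columns, 1-based facility and county membership indices and an optional
positive survey weight. A JSON schema maps each covariate column to its
coefficient block — ``b`` (patient), ``s`` (facility binary/continuous),
``q`` (county continuous), ``m`` (patient/facility mixed) — mirroring the
coefficient blocks of the hierarchical model, with block-specific prior
precisions.

No intercept column is permitted: the cutpoints absorb the location of the
latent scale, so a constant column would be unidentifiable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OrdinalDataset"]

_RESERVED = ("outcome", "facility_id", "county_id", "weight")


@dataclass
class OrdinalDataset:
    """In-memory analysis dataset.

    Attributes
    ----------
    y : ndarray of int
        Outcome per patient, values in 1..K.
    X : ndarray, shape (n, p)
        Dummy-expanded fixed-effect design (no intercept).
    columns : list[str]
        Names of the columns of ``X``.
    blocks : dict[str, str]
        Coefficient block (``b``/``s``/``q``/``m``) per column.
    facility_index, county_index : ndarray of int
        1-based membership indices.
    weight : ndarray or None
        Positive per-patient weights; ``None`` means unit weights.
    """

    y: np.ndarray
    X: np.ndarray
    columns: list
    blocks: dict
    facility_index: np.ndarray
    county_index: np.ndarray
    weight: np.ndarray = None
    n_categories: int = 3
    n_facilities: int = field(default=None)
    n_counties: int = field(default=None)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=int)
        self.X = np.asarray(self.X, dtype=float)
        self.facility_index = np.asarray(self.facility_index, dtype=int)
        self.county_index = np.asarray(self.county_index, dtype=int)
        if self.weight is not None:
            self.weight = np.asarray(self.weight, dtype=float)
        if self.n_facilities is None:
            self.n_facilities = int(self.facility_index.max()) if self.n > 0 else 0
        if self.n_counties is None:
            self.n_counties = int(self.county_index.max()) if self.n > 0 else 0
        self.validate()

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1] if self.X.ndim == 2 else 0

    def validate(self) -> None:
        n = self.n
        if self.X.shape[0] != n:
            raise ValueError("X and y row counts differ")
        if len(self.columns) != self.p:
            raise ValueError("column names do not match X width")
        if n == 0:
            return
        if self.y.min() < 1 or self.y.max() > self.n_categories:
            raise ValueError(
                f"outcome values must lie in 1..{self.n_categories}"
            )
        if self.facility_index.min() < 1 or self.facility_index.max() > self.n_facilities:
            raise ValueError("facility_index out of range")
        if self.county_index.min() < 1 or self.county_index.max() > self.n_counties:
            raise ValueError("county_index out of range")
        if self.weight is not None and np.any(self.weight <= 0):
            raise ValueError("weights must be strictly positive")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")
        for k, name in enumerate(self.columns):
            if n > 1 and np.ptp(self.X[:, k]) == 0:
                raise ValueError(
                    f"column {name!r} is constant; intercepts are absorbed by the "
                    "cutpoints and constant columns are not identifiable"
                )
        unknown = [c for c, blk in self.blocks.items() if blk not in ("b", "s", "q", "m")]
        if unknown:
            raise ValueError(f"unknown coefficient block for columns {unknown}")

    def block_of(self, column: str) -> str:
        return self.blocks.get(column, "b")

    def subset_columns(self, keep) -> "OrdinalDataset":
        """New dataset restricted to the covariate columns in ``keep``."""
        idx = [self.columns.index(c) for c in keep]
        return OrdinalDataset(
            y=self.y,
            X=self.X[:, idx],
            columns=list(keep),
            blocks={c: self.blocks[c] for c in keep},
            facility_index=self.facility_index,
            county_index=self.county_index,
            weight=self.weight,
            n_categories=self.n_categories,
            n_facilities=self.n_facilities,
            n_counties=self.n_counties,
        )

    # -- pandas interop -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.columns)
        df.insert(0, "outcome", self.y)
        df["facility_id"] = self.facility_index
        df["county_id"] = self.county_index
        df["weight"] = self.weight if self.weight is not None else 1.0
        return df

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        blocks: dict,
        outcome: str = "outcome",
        facility: str = "facility_id",
        county: str = "county_id",
        weight: str = "weight",
        n_categories: int = 3,
        n_facilities: int = None,
        n_counties: int = None,
    ) -> "OrdinalDataset":
        covariates = [c for c in df.columns if c not in (outcome, facility, county, weight)]
        w = None
        if weight in df.columns:
            w = df[weight].to_numpy(dtype=float)
            if np.allclose(w, 1.0):
                w = None
        return cls(
            y=df[outcome].to_numpy(),
            X=df[covariates].to_numpy(dtype=float),
            columns=covariates,
            blocks={c: blocks.get(c, "b") for c in covariates},
            facility_index=df[facility].to_numpy(),
            county_index=df[county].to_numpy(),
            weight=w,
            n_categories=n_categories,
            n_facilities=n_facilities,
            n_counties=n_counties,
        )

    # -- delimited-text round trip --------------------------------------
    def to_csv(self, path, schema_path=None) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")
        if schema_path is not None:
            schema = {
                "n_categories": self.n_categories,
                "n_facilities": self.n_facilities,
                "n_counties": self.n_counties,
                "blocks": self.blocks,
            }
            with open(schema_path, "w") as fh:
                json.dump(schema, fh, indent=1)

    @classmethod
    def from_csv(cls, path, schema_path=None, blocks=None, **kwargs) -> "OrdinalDataset":
        df = pd.read_csv(path, float_precision="round_trip")
        if schema_path is not None:
            with open(schema_path) as fh:
                schema = json.load(fh)
            blocks = schema["blocks"]
            kwargs.setdefault("n_categories", schema["n_categories"])
            kwargs.setdefault("n_facilities", schema["n_facilities"])
            kwargs.setdefault("n_counties", schema["n_counties"])
        return cls.from_frame(df, blocks=blocks or {}, **kwargs)

    def fingerprint(self) -> str:
        """Stable content hash used to tie stored draws back to their data."""
        h = hashlib.sha256()
        h.update(self.y.tobytes())
        h.update(np.ascontiguousarray(self.X).tobytes())
        h.update(self.facility_index.tobytes())
        h.update(self.county_index.tobytes())
        h.update(",".join(self.columns).encode())
        return h.hexdigest()[:16]
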