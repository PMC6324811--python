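"""Count-dataset container, delimited-text ingestion and test fixtures.

The modelling functions consume a :class:`CountDataset`: a non-negative
integer response (e.g. micronucleated binucleated cells per subject), a
positive exposure (cells scored, entering the model as a log offset), a
small unpenalized design (covariates forced into the model, e.g. gender)
and a large penalized design (e.g. gene expression) subject to selection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("nbgmifs")


@dataclass
class CountDataset:
    """Validated inputs for a penalized count regression.

    Attributes
    ----------
    y : ndarray
        Non-negative integer counts, length N.
    exposure : ndarray
        Positive exposures c, length N; enters the model as ``log(c)``.
    X_unpenalized : ndarray
        N x J design of covariates forced into the model (J may be 0).
    X_penalized : ndarray
        N x K design of covariates subject to selection (K may be 0).
    """

    y: np.ndarray
    exposure: np.ndarray | None = None
    X_unpenalized: np.ndarray | None = None
    X_penalized: np.ndarray | None = None
    feature_names: list[str] | None = None
    unpenalized_names: list[str] | None = None
    row_ids: list[str] | None = None

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        if y.ndim != 1:
            raise ValueError("y must be a 1-d vector of counts")
        if np.any(~np.isfinite(y)) or np.any(y < 0) or np.any(y != np.floor(y)):
            raise ValueError("y must contain finite non-negative integers")
        self.y = y
        n = y.shape[0]
        if self.exposure is None:
            self.exposure = np.ones(n)
        else:
            c = np.asarray(self.exposure, dtype=float)
            if c.shape != (n,):
                raise ValueError("exposure length must match y")
            if np.any(~np.isfinite(c)) or np.any(c <= 0):
                raise ValueError("exposures must be positive and finite")
            self.exposure = c
        for attr in ("X_unpenalized", "X_penalized"):
            X = getattr(self, attr)
            if X is None:
                setattr(self, attr, np.empty((n, 0)))
            else:
                X = np.atleast_2d(np.asarray(X, dtype=float))
                if X.shape[0] != n:
                    raise ValueError(f"{attr} row count must match y")
                if np.any(~np.isfinite(X)):
                    raise ValueError(f"{attr} contains missing/non-finite values")
                setattr(self, attr, X)
        if self.feature_names is None:
            self.feature_names = [f"x{k}" for k in range(self.X_penalized.shape[1])]
        elif len(self.feature_names) != self.X_penalized.shape[1]:
            raise ValueError("feature_names length must match penalized columns")
        if self.unpenalized_names is None:
            self.unpenalized_names = [
                f"u{j}" for j in range(self.X_unpenalized.shape[1])
            ]
        if self.row_ids is None:
            self.row_ids = [f"s{i}" for i in range(n)]

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def offset(self) -> np.ndarray:
        """Log exposure, the fixed-coefficient offset of the rate model."""
        return np.log(self.exposure)


def read_count_dataset(
    response_path,
    matrix_path=None,
    *,
    response_col: str = "y",
    exposure_col: str | None = None,
    unpenalized_cols: tuple[str, ...] = (),
    orientation: str = "samples_by_features",
    round_counts: bool = False,
) -> CountDataset:
    """Read a :class:`CountDataset` from delimited text files.

    ``response_path`` is a CSV/TSV table with one row per sample holding the
    response column, and optionally exposure and unpenalized-covariate
    columns.  ``matrix_path`` (optional) is the penalized feature matrix,
    either samples x features or features x samples per ``orientation`` —
    never auto-detected.  Features with any missing value are dropped, with
    the count logged.

    Raises
    ------
    ValueError
        Missing columns, non-integer counts (unless ``round_counts``),
        non-positive exposures, or duplicate feature names.
    """
    if orientation not in ("samples_by_features", "features_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep_r = "\t" if str(response_path).endswith((".tsv", ".txt")) else ","
    resp = pd.read_csv(response_path, sep=sep_r)
    if response_col not in resp.columns:
        raise ValueError(f"response column {response_col!r} not found")
    y = resp[response_col].to_numpy(dtype=float)
    if np.any(y != np.floor(y)):
        if round_counts:
            logger.warning("rounding non-integer counts to nearest integer")
            y = np.round(y)
        else:
            raise ValueError(
                "response contains non-integer counts (pass round_counts=True "
                "to round, with a warning)"
            )
    exposure = None
    if exposure_col is not None:
        if exposure_col not in resp.columns:
            raise ValueError(f"exposure column {exposure_col!r} not found")
        exposure = resp[exposure_col].to_numpy(dtype=float)
        if np.any(exposure <= 0):
            raise ValueError("exposures must be strictly positive")
    missing_u = [c for c in unpenalized_cols if c not in resp.columns]
    if missing_u:
        raise ValueError(f"unpenalized columns not found: {missing_u}")
    Xu = resp[list(unpenalized_cols)].to_numpy(dtype=float) if unpenalized_cols else None

    Xp = None
    feature_names = None
    if matrix_path is not None:
        sep_m = "\t" if str(matrix_path).endswith((".tsv", ".txt")) else ","
        # pandas mangles duplicate header names, so check the raw header
        with open(matrix_path) as fh:
            header = fh.readline().rstrip("\n").split(sep_m)[1:]
        if orientation == "samples_by_features" and len(header) != len(set(header)):
            dups = sorted({h for h in header if header.count(h) > 1})
            raise ValueError(f"duplicate feature names: {dups}")
        mat = pd.read_csv(matrix_path, sep=sep_m, index_col=0)
        if orientation == "features_by_samples":
            mat = mat.T
            if mat.columns.duplicated().any():
                dups = sorted(set(mat.columns[mat.columns.duplicated()]))
                raise ValueError(f"duplicate feature names: {dups}")
        n_before = mat.shape[1]
        mat = mat.dropna(axis=1)
        dropped = n_before - mat.shape[1]
        if dropped:
            logger.info(
                "dropped %d feature(s) with missing values; %d retained",
                dropped,
                mat.shape[1],
            )
        if mat.shape[0] != len(y):
            raise ValueError(
                f"feature matrix has {mat.shape[0]} samples but response has {len(y)}"
            )
        Xp = mat.to_numpy(dtype=float)
        feature_names = [str(c) for c in mat.columns]

    row_ids = [str(r) for r in resp.index]
    return CountDataset(
        y=y,
        exposure=exposure,
        X_unpenalized=Xu,
        X_penalized=Xp,
        feature_names=feature_names,
        unpenalized_names=list(unpenalized_cols),
        row_ids=row_ids,
    )


FIXTURE_KINDS = ("poisson_small", "negbin_small", "negbin_offset", "missingness")


def generate_fixture(kind: str, seed: int, out_dir) -> dict:
    """Write a small synthetic dataset with known generating parameters.

    Produces ``response.csv`` (response, exposure, gender), ``features.csv``
    (samples x features) and a ``truth.json`` sidecar recording the true
    (gamma0, gamma, beta, alpha, seed).  Deterministic for a given seed.
    """
    from .families import nb_sample

    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n, k = 40, 20
    gamma0, gamma_gender = 0.5, 0.4
    beta = np.zeros(k)
    beta[[0, 3, 7]] = [0.6, -0.6, 0.5]
    alpha = 0.0 if kind == "poisson_small" else 0.5
    X = rng.standard_normal((n, k))
    gender = rng.integers(0, 2, size=n).astype(float)
    if kind == "negbin_offset":
        exposure = rng.choice([500.0, 1000.0, 2000.0], size=n)
        # rate per cell scored; keep expected counts in a realistic range
        gamma0 = np.log(5.0 / 1000.0)
    else:
        exposure = np.ones(n)
    mu = exposure * np.exp(gamma0 + gamma_gender * gender + X @ beta)
    y = nb_sample(mu, alpha, rng)

    feat = pd.DataFrame(X, columns=[f"g{j:03d}" for j in range(k)])
    if kind == "missingness":
        feat.loc[feat.index[2], "g005"] = np.nan
        feat.loc[feat.index[11], "g013"] = np.nan
    feat.insert(0, "sample", [f"s{i}" for i in range(n)])
    resp = pd.DataFrame(
        {
            "sample": [f"s{i}" for i in range(n)],
            "y": y.astype(int),
            "cells_scored": exposure.astype(int),
            "gender": gender.astype(int),
        }
    )
    resp.to_csv(out_dir / "response.csv", index=False)
    feat.to_csv(out_dir / "features.csv", index=False)
    truth = {
        "kind": kind,
        "seed": int(seed),
        "gamma0": float(gamma0),
        "gamma": [float(gamma_gender)],
        "beta": [float(b) for b in beta],
        "alpha": float(alpha),
        "n": n,
        "k": k,
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth
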