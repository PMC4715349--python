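"""One-class classification of candidate SVs against random-region training.

The training class is a set of random genomic regions — coordinates
unlikely to sit near a true SV — annotated exactly like the candidates.
Two one-class models are provided, both exposed statsmodels-style as a
model object whose ``fit()`` returns a results object:

* :class:`L1OneClassModel`: after the asinh/standardise transform, compute
  the training mean vector M and the empirical distribution of L1
  distances of the training sites from M.  The acceptance region R at
  level p is the L1 ball {x : d(x, M) <= t_p}, a multidimensional rhombus,
  where t_p is the empirical p-quantile of training distances.  A
  candidate is called an SV when its distance exceeds t_p.  The ρ score of
  a site is the proportion of training sites strictly closer to M — a
  uniform [0,1) score on training-like data, so high ρ means strong SV
  evidence.

* :class:`SVMOneClassModel`: the ν-parameterised one-class SVM of
  Schölkopf with a linear kernel, trained at each ν on a grid after a
  per-annotation directional transform (u = 1 - ECDF of the deviation in
  the direction of interest, so deviant sites sit near 0).  The score of a
  site is the smallest training true-negative rate (1-ν) whose boundary
  still contains the site; a site outside every boundary scores 1
  (maximally outlying), mirroring ρ.

Per-technology classifiers are combined either by concatenating the
annotation vectors into one model or by a k-of-n ensemble vote.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skmetrics
from sklearn.svm import OneClassSVM as _SkOneClassSVM

from .core import AnnotationTable
from .transform import TransformModel, apply_transform, fit_transform_model

__all__ = [
    "L1OneClassModel",
    "L1OneClassResults",
    "SVMOneClassModel",
    "SVMOneClassResults",
    "fit_l1_model",
    "rho_score",
    "classify_l1",
    "fit_svm_model",
    "svm_score",
    "ensemble_vote",
    "ensemble_rho",
    "prefilter_sites",
    "stratify",
    "roc_curve",
    "TABLE_STRATA",
    "DEFAULT_NU_GRID",
    "default_directions",
]

#: ρ strata used for reporting confidence tiers.
TABLE_STRATA = (0.68, 0.9, 0.97, 0.99, 0.997, 0.999)

#: ν grid for the one-class SVM (training outlier fractions).
DEFAULT_NU_GRID = (0.01, 0.02, 0.05, 0.1, 0.2, 0.32, 0.5)


# ---------------------------------------------------------------------------
# L1 empirical-distance classifier
# ---------------------------------------------------------------------------

class L1OneClassModel:
    """L1 distance-to-centroid one-class model over an annotation table.

    Parameters
    ----------
    training:
        Annotation table of random (non-SV) regions on the raw scale.
    transform:
        Frozen standardisation parameters; fitted on ``training`` when
        omitted.
    min_train:
        Guard against unusably small training sets (overridable).
    """

    def __init__(
        self,
        training: AnnotationTable,
        transform: TransformModel | None = None,
        min_train: int = 100,
    ) -> None:
        if len(training) < min_train:
            raise ValueError(
                f"training set has {len(training)} rows; need >= {min_train}"
            )
        self.training = training
        self.transform = transform if transform is not None else fit_transform_model(training)

    def fit(self) -> "L1OneClassResults":
        z = apply_transform(self.transform, self.training)
        x = z.values.to_numpy()
        mean = x.mean(axis=0)
        dists = np.abs(x - mean).sum(axis=1)
        return L1OneClassResults(
            mean=pd.Series(mean, index=z.annotation_names),
            train_distances=np.sort(dists),
            transform=self.transform,
        )


@dataclass
class L1OneClassResults:
    """Fitted L1 one-class classifier: centroid, training distances, thresholds."""

    mean: pd.Series
    train_distances: np.ndarray  # sorted ascending
    transform: TransformModel

    @property
    def n_train(self) -> int:
        return len(self.train_distances)

    @property
    def annotation_names(self) -> list[str]:
        return list(self.mean.index)

    def threshold(self, p: float) -> float:
        """t_p: smallest training distance with >= p*n_train distances <= it."""
        if not (0 < p < 1):
            raise ValueError("p must be in (0, 1)")
        k = math.ceil(p * self.n_train)
        return float(self.train_distances[k - 1])

    def _to_matrix(self, sites) -> np.ndarray:
        if isinstance(sites, AnnotationTable):
            z = apply_transform(self.transform, sites)
            return z.values[self.annotation_names].to_numpy()
        arr = np.atleast_2d(np.asarray(sites, dtype=float))
        if arr.shape[1] != len(self.mean):
            raise ValueError(
                f"site vector has {arr.shape[1]} annotations; model has {len(self.mean)}"
            )
        return arr

    def distances(self, sites) -> np.ndarray:
        """L1 distance of each (already- or to-be-transformed) site from M.

        Raw :class:`AnnotationTable` inputs are passed through the frozen
        transform; bare arrays are assumed already standardised.
        """
        x = self._to_matrix(sites)
        return np.abs(x - self.mean.to_numpy()).sum(axis=1)

    def rho(self, sites) -> np.ndarray:
        """Proportion of training sites strictly closer to the centroid."""
        d = self.distances(sites)
        return np.searchsorted(self.train_distances, d, side="left") / self.n_train

    def classify(self, sites, p: float = 0.95) -> np.ndarray:
        """True where the site is called an SV: d > t_p (ties -> non-SV)."""
        return self.distances(sites) > self.threshold(p)

    def summary(self) -> str:
        lines = [
            "L1 one-class classifier",
            "=======================",
            f"training sites      : {self.n_train}",
            f"annotations         : {len(self.mean)}",
            f"median train L1 dist: {np.median(self.train_distances):.4g}",
            "thresholds t_p      : "
            + ", ".join(f"p={p}: {self.threshold(p):.4g}" for p in (0.9, 0.95, 0.99)),
        ]
        return "\n".join(lines)


def fit_l1_model(
    training: AnnotationTable,
    transform: TransformModel | None = None,
    min_train: int = 100,
) -> L1OneClassResults:
    return L1OneClassModel(training, transform, min_train).fit()


def rho_score(model: L1OneClassResults, site_vector) -> np.ndarray | float:
    r = model.rho(site_vector)
    return float(r[0]) if np.ndim(site_vector) == 1 else r


def classify_l1(model: L1OneClassResults, site_vector, p: float) -> np.ndarray | bool:
    c = model.classify(site_vector, p)
    return bool(c[0]) if np.ndim(site_vector) == 1 else c


def fit_combined_l1(
    training_tables: Mapping[str, AnnotationTable],
    min_train: int = 100,
) -> L1OneClassResults:
    """All-datasets model: concatenate per-dataset annotation vectors."""
    combined = AnnotationTable.concat_columns(dict(training_tables))
    return fit_l1_model(combined, min_train=min_train)


# ---------------------------------------------------------------------------
# one-class SVM variant
# ---------------------------------------------------------------------------

def default_directions(annotation_names: Sequence[str]) -> dict[str, str]:
    """Deviation direction of interest per annotation, by name pattern.

    Depth drops at deletions (low is deviant); clipping, discordance,
    mate-unmapped and insert statistics rise near breakpoints (high is
    deviant); the long-read del-ins difference moves either way depending
    on the SV type (two-sided).
    """
    out: dict[str, str] = {}
    for name in annotation_names:
        base = name.split("__")[-1]
        if base.endswith(("_Cov", "_ReadCount")):
            out[name] = "low_is_deviant"
        elif "DelMinusIns" in base:
            out[name] = "two_sided"
        else:
            out[name] = "high_is_deviant"
    return out


class SVMOneClassModel:
    """ν-grid one-class SVM over directionally ECDF-transformed annotations."""

    def __init__(
        self,
        training: AnnotationTable,
        directions: Mapping[str, str] | None = None,
        nu_grid: Sequence[float] = DEFAULT_NU_GRID,
        random_state: int = 0,
    ) -> None:
        nu_grid = tuple(nu_grid)
        if any(not (0 < nu < 1) for nu in nu_grid):
            raise ValueError("every nu must be in (0, 1)")
        if list(nu_grid) != sorted(nu_grid) or len(set(nu_grid)) != len(nu_grid):
            raise ValueError("nu grid must be strictly increasing")
        self.training = training
        self.directions = dict(
            directions
            if directions is not None
            else default_directions(training.annotation_names)
        )
        missing = [c for c in training.annotation_names if c not in self.directions]
        if missing:
            raise ValueError(f"no deviation direction for: {missing}")
        self.nu_grid = nu_grid
        self.random_state = random_state

    def fit(self) -> "SVMOneClassResults":
        train_dev = self._deviations(self.training)
        u_train = self._ecdf_transform(train_dev, train_dev)
        svms = []
        for nu in self.nu_grid:
            clf = _SkOneClassSVM(kernel="linear", nu=nu)
            clf.fit(u_train.to_numpy())
            svms.append(clf)
        return SVMOneClassResults(
            model=self,
            train_deviations=train_dev,
            svms=tuple(svms),
        )

    # -- transforms -------------------------------------------------------
    def _deviations(self, table: AnnotationTable) -> pd.DataFrame:
        """Directional deviation per annotation (higher = more deviant)."""
        x = table.filled(np.nan)[list(self.training.annotation_names)]
        ref_median = self.training.filled(np.nan).median(axis=0, skipna=True)
        dev = pd.DataFrame(index=x.index, dtype=float)
        for col in x.columns:
            direction = self.directions[col]
            if direction == "low_is_deviant":
                dev[col] = -x[col]
            elif direction == "high_is_deviant":
                dev[col] = x[col]
            elif direction == "two_sided":
                dev[col] = (x[col] - ref_median[col]).abs()
            else:
                raise ValueError(f"unknown direction {direction!r} for {col}")
        return dev

    def _ecdf_transform(self, dev: pd.DataFrame, train_dev: pd.DataFrame) -> pd.DataFrame:
        """u = 1 - (# training deviations strictly below) / n, in (0, 1].

        The most deviant training value maps to 1/n (near 0), the least to
        1.  Masked cells map to 1 (no evidence of deviation).
        """
        n = len(train_dev)
        u = pd.DataFrame(index=dev.index, dtype=float)
        for col in dev.columns:
            ref = np.sort(train_dev[col].dropna().to_numpy())
            vals = dev[col].to_numpy()
            ranks = np.searchsorted(ref, vals, side="left")
            ucol = 1.0 - ranks / max(len(ref), 1)
            ucol[np.isnan(vals)] = 1.0
            u[col] = ucol
        return u


@dataclass
class SVMOneClassResults:
    """Fitted ν-grid of one-class SVM boundaries plus the shared transform."""

    model: SVMOneClassModel
    train_deviations: pd.DataFrame
    svms: tuple

    @property
    def nu_grid(self) -> tuple[float, ...]:
        return self.model.nu_grid

    def _u(self, table: AnnotationTable) -> np.ndarray:
        dev = self.model._deviations(table)
        return self.model._ecdf_transform(dev, self.train_deviations).to_numpy()

    def inside(self, table: AnnotationTable) -> np.ndarray:
        """Boolean matrix (sites x nu grid): inside the boundary at each ν."""
        u = self._u(table)
        cols = [clf.predict(u) == 1 for clf in self.svms]
        return np.column_stack(cols)

    def score(self, table: AnnotationTable) -> np.ndarray:
        """Smallest training true-negative rate (1-ν) whose boundary still
        contains the site; 1.0 when outside at every ν (maximally
        outlying).  High scores mean strong SV evidence, like ρ."""
        ins = self.inside(table)
        tnr = 1.0 - np.asarray(self.nu_grid)
        scores = np.ones(len(ins))
        for i, row in enumerate(ins):
            if row.any():
                scores[i] = tnr[row].min()
        return scores

    def classify(self, table: AnnotationTable, p: float = 0.95) -> np.ndarray:
        """SV call at level p: outside every boundary with TNR >= p."""
        return self.score(table) > p

    def summary(self) -> str:
        frac_out = []
        ins = self.inside(self.model.training)
        for j, nu in enumerate(self.nu_grid):
            frac_out.append(f"nu={nu}: {1 - ins[:, j].mean():.3f}")
        return "\n".join(
            [
                "One-class SVM (linear kernel, nu grid)",
                "======================================",
                f"training sites: {len(self.train_deviations)}",
                f"annotations   : {self.train_deviations.shape[1]}",
                "train outlier fraction " + ", ".join(frac_out),
            ]
        )


def fit_svm_model(
    training: AnnotationTable,
    directions: Mapping[str, str] | None = None,
    nu_grid: Sequence[float] = DEFAULT_NU_GRID,
) -> SVMOneClassResults:
    return SVMOneClassModel(training, directions, nu_grid).fit()


def svm_score(model: SVMOneClassResults, table: AnnotationTable) -> np.ndarray:
    return model.score(table)


# ---------------------------------------------------------------------------
# ensembles, pre-filters, stratification, ROC
# ---------------------------------------------------------------------------

def ensemble_vote(per_dataset_calls: Sequence[bool], k: int) -> bool:
    """SV iff at least k of the per-dataset classifiers call SV."""
    n = len(per_dataset_calls)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}]")
    return int(np.sum(per_dataset_calls)) >= k


def ensemble_rho(per_dataset_rhos: np.ndarray, k: int) -> np.ndarray:
    """k-th largest per-dataset ρ per site.

    The k-th largest ρ exceeds p exactly when at least k datasets have
    ρ > p, so thresholding this score reproduces the k-of-n vote at every
    level simultaneously.
    """
    arr = np.atleast_2d(np.asarray(per_dataset_rhos, dtype=float))
    n = arr.shape[1]
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}]")
    return np.sort(arr, axis=1)[:, n - k]


def prefilter_sites(
    flank_stats: pd.DataFrame,
    max_flank_coverage: float = 300.0,
    min_flank_mapq: float = 30.0,
) -> pd.DataFrame:
    """Flag sites in regions where the classifier may mislead.

    ``high_flank_coverage``: depth above the threshold in BOTH flanks
    (likely inside a duplicated region).  ``low_flank_mapq``: mean mapping
    quality below the threshold in EITHER flank.  ``flank_stats`` needs
    columns L_Cov, R_Cov, L_MapQ, R_MapQ; a site with any of those masked
    is flagged ``unfilterable``.
    """
    need = ["L_Cov", "R_Cov", "L_MapQ", "R_MapQ"]
    missing = [c for c in need if c not in flank_stats.columns]
    if missing:
        raise KeyError(f"flank stats lack columns: {missing}")
    s = flank_stats[need]
    unfilterable = s.isna().any(axis=1)
    high_cov = (s["L_Cov"] > max_flank_coverage) & (s["R_Cov"] > max_flank_coverage)
    low_mapq = (s["L_MapQ"] < min_flank_mapq) | (s["R_MapQ"] < min_flank_mapq)
    return pd.DataFrame(
        {
            "high_flank_coverage": high_cov & ~unfilterable,
            "low_flank_mapq": low_mapq & ~unfilterable,
            "unfilterable": unfilterable,
        },
        index=flank_stats.index,
    )


def stratify(
    rhos: Sequence[float], boundaries: Sequence[float] = TABLE_STRATA
) -> list[str]:
    """Bin ρ scores into confidence strata.

    Bins are half-open [b_i, b_{i+1}); the lowest is ``<b_0`` and the top
    bin ``>b_last`` is closed at 1.
    """
    bounds = list(boundaries)
    if bounds != sorted(bounds):
        raise ValueError("boundaries must be sorted")
    names = [f"<{bounds[0]}"]
    names += [f"{a}-{b}" for a, b in zip(bounds[:-1], bounds[1:])]
    names += [f">{bounds[-1]}"]
    out = []
    for r in np.asarray(rhos, dtype=float):
        idx = int(np.searchsorted(bounds, r, side="right"))
        out.append(names[idx])
    return out


def roc_curve(
    scores_positive: Sequence[float], scores_negative: Sequence[float]
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC sweeping score thresholds (ties grouped): (fpr, tpr, auc)."""
    pos = np.asarray(scores_positive, dtype=float)
    neg = np.asarray(scores_negative, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score lists must be non-empty")
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    s = np.concatenate([pos, neg])
    fpr, tpr, _ = _skmetrics.roc_curve(y, s)
    return fpr, tpr, float(_skmetrics.auc(fpr, tpr))
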