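"""Inductive and cross-conformal regression.

An inductive conformal predictor (ICP) splits the training data into a
*proper training set*, used to fit the endpoint model (and, for normalized
measures, an error model), and a *calibration set*, on which a
nonconformity score alpha is computed for every compound and sorted
ascending.  At prediction time the alpha found at the requested confidence
rank is converted back into an interval half-width by inverting the
nonconformity measure, giving a symmetric interval around the endpoint
prediction.  Under exchangeability the interval covers the truth with at
least the nominal probability.

Three nonconformity measures are supported:

``abs_diff``        alpha = |y - y_hat|                (constant widths)
``normalized``      alpha = |y - y_hat| / mu_hat       (per-compound widths)
``log_normalized``  alpha = |y - y_hat| / (e^mu_hat + beta)

where mu_hat is the prediction of an error model trained on the magnitude
(resp. log-magnitude) of the endpoint residuals, and beta >= 0 smooths the
log-normalized widths toward constancy.

A cross-conformal predictor (CCP) repeats the split in a k-fold fashion
(default k=10): member i calibrates on fold i and trains on the rest.  A
prediction aggregates the k member intervals by median midpoint and median
interval width.
"""

from __future__ import annotations

import json
import math
import tarfile
from dataclasses import dataclass
from io import BytesIO
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    ConfigError,
    EmptyCalibrationError,
    InsufficientDataError,
)
from .linear_model import (
    LinearModel,
    SvrParams,
    fit_svr,
    predict,
    predict_many,
    vectors_to_csr,
)
from .signatures import FeatureVector, SignatureVocabulary

INFINITE = math.inf

_KINDS = ("abs_diff", "normalized", "log_normalized")


@dataclass(frozen=True)
class NonconformityConfig:
    """Choice and parameters of the nonconformity measure.

    beta is used only by log_normalized; mu_floor floors the normalized
    denominator (a linear error model can predict <= 0); err_floor floors
    |residual| inside the log when building log_normalized error targets.
    """

    kind: str = "normalized"
    beta: float = 0.0
    mu_floor: float = 1e-8
    err_floor: float = 1e-8

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ConfigError(f"unknown nonconformity kind: {self.kind!r}")
        if self.beta < 0 or self.mu_floor <= 0 or self.err_floor <= 0:
            raise ConfigError("beta >= 0 and positive floors required")

    @property
    def needs_error_model(self) -> bool:
        return self.kind != "abs_diff"


@dataclass
class PredictionInterval:
    """Symmetric prediction interval around the endpoint midpoint."""

    midpoint: float
    lower: float
    upper: float
    confidence: float

    @property
    def width(self) -> float:
        return self.upper - self.lower

    @property
    def unbounded(self) -> bool:
        return not math.isfinite(self.width)

    @classmethod
    def from_half_width(cls, midpoint: float, half: float,
                        confidence: float) -> "PredictionInterval":
        return cls(midpoint, midpoint - half, midpoint + half, confidence)


def nonconformity(y: float, y_hat: float, mu_hat: float | None,
                  ncm: NonconformityConfig) -> float:
    """Nonconformity score of a (label, prediction) pair."""
    err = abs(y - y_hat)
    if ncm.kind == "abs_diff":
        return err
    if mu_hat is None:
        raise ConfigError(f"{ncm.kind} requires an error-model prediction")
    if ncm.kind == "normalized":
        return err / max(mu_hat, ncm.mu_floor)
    return err / (math.exp(mu_hat) + ncm.beta)


def half_width_from_alpha(alpha: float, mu_hat: float | None,
                          ncm: NonconformityConfig) -> float:
    """Invert the nonconformity measure: solve for |y - y_hat|."""
    if not math.isfinite(alpha):
        return INFINITE
    if ncm.kind == "abs_diff":
        return alpha
    if mu_hat is None:
        raise ConfigError(f"{ncm.kind} requires an error-model prediction")
    if ncm.kind == "normalized":
        return alpha * max(mu_hat, ncm.mu_floor)
    return alpha * (math.exp(mu_hat) + ncm.beta)


def alpha_at_confidence(alphas: Sequence[float], confidence: float) -> float:
    """Alpha at 1-based rank ceil(confidence * (n + 1)) of the ascending
    list; INFINITE when the rank exceeds n (the interval is unbounded)."""
    n = len(alphas)
    if n == 0:
        raise EmptyCalibrationError("empty calibration alpha list")
    if not (0 < confidence < 1):
        raise ValueError("confidence must lie in (0, 1)")
    rank = math.ceil(confidence * (n + 1))
    if rank > n:
        return INFINITE
    return float(alphas[rank - 1])


@dataclass
class IcpModel:
    """One inductive conformal predictor."""

    endpoint: LinearModel
    error_model: LinearModel | None
    alphas: np.ndarray
    ncm: NonconformityConfig

    def __post_init__(self):
        if self.ncm.needs_error_model != (self.error_model is not None):
            raise ConfigError(
                "error model must be present iff the measure needs one"
            )


def _error_targets(residuals: np.ndarray,
                   ncm: NonconformityConfig) -> np.ndarray:
    err = np.abs(residuals)
    if ncm.kind == "normalized":
        return err
    return np.log(np.maximum(err, ncm.err_floor))


def icp_fit(
    proper: tuple,
    calibration: tuple,
    params: SvrParams = SvrParams(),
    ncm: NonconformityConfig = NonconformityConfig(),
    n_features: int | None = None,
) -> IcpModel:
    """Fit one ICP: endpoint (and error) models on the proper set, alphas
    on the calibration set.

    Error-model targets are the in-sample endpoint residual magnitudes on
    the proper training set (log-magnitudes for log_normalized).
    """
    Xp, yp = proper
    Xc, yc = calibration
    Xp = vectors_to_csr(Xp, n_features)
    Xc = vectors_to_csr(Xc, Xp.shape[1])
    yp = np.asarray(yp, float)
    yc = np.asarray(yc, float)
    if Xp.shape[0] == 0 or Xc.shape[0] == 0:
        raise InsufficientDataError("proper and calibration must be non-empty")

    endpoint = fit_svr(Xp, yp, params)
    error_model = None
    mu_cal = None
    if ncm.needs_error_model:
        resid = yp - predict_many(endpoint, Xp)
        error_model = fit_svr(Xp, _error_targets(resid, ncm), params)
        mu_cal = predict_many(error_model, Xc)

    yc_hat = predict_many(endpoint, Xc)
    alphas = np.array([
        nonconformity(y, y_hat, None if mu_cal is None else mu_cal[i], ncm)
        for i, (y, y_hat) in enumerate(zip(yc, yc_hat))
    ])
    alphas.sort()
    return IcpModel(endpoint=endpoint, error_model=error_model,
                    alphas=alphas, ncm=ncm)


def icp_predict(icp: IcpModel, x: FeatureVector | dict,
                confidence: float) -> PredictionInterval:
    """Predict a symmetric interval at the requested confidence."""
    y_hat = predict(icp.endpoint, x)
    mu_hat = (
        predict(icp.error_model, x) if icp.error_model is not None else None
    )
    alpha = alpha_at_confidence(icp.alphas, confidence)
    half = half_width_from_alpha(alpha, mu_hat, icp.ncm)
    return PredictionInterval.from_half_width(y_hat, half, confidence)


@dataclass
class CcpModel:
    """k aggregated ICPs with median-combination at prediction time."""

    members: list[IcpModel]
    vocabulary: SignatureVocabulary | None
    seed: int
    heights: tuple[int, ...] = (1, 2, 3)

    @property
    def k(self) -> int:
        return len(self.members)

    @property
    def ncm(self) -> NonconformityConfig:
        return self.members[0].ncm


def fold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded random permutation split into k non-overlapping folds of
    size floor(n/k) or ceil(n/k)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(perm, k)]


def ccp_fit(
    train: tuple,
    k: int = 10,
    params: SvrParams = SvrParams(),
    ncm: NonconformityConfig = NonconformityConfig(),
    seed: int = 42,
    vocabulary: SignatureVocabulary | None = None,
    n_features: int | None = None,
) -> CcpModel:
    """Fit a k-fold cross-conformal predictor.

    Member i uses fold i as its calibration set and the remaining folds as
    its proper training set.  With k=1 the single member uses a seeded
    80/20 proper/calibration split instead (a one-split ICP).
    """
    X, y = train
    if n_features is None and vocabulary is not None:
        n_features = len(vocabulary)
    Xm = vectors_to_csr(X, n_features)
    y = np.asarray(y, float)
    n = Xm.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < 2 * k or n < 5:
        raise InsufficientDataError(
            f"need at least max(2k, 5) = {max(2 * k, 5)} samples, got {n}"
        )

    if k == 1:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        n_cal = max(1, int(round(0.2 * n)))
        folds = [np.sort(perm[:n_cal])]
        rests = [np.sort(perm[n_cal:])]
    else:
        folds = fold_indices(n, k, seed)
        all_idx = np.arange(n)
        rests = [np.setdiff1d(all_idx, f) for f in folds]

    members = []
    for fold, rest in zip(folds, rests):
        members.append(
            icp_fit(
                (Xm[rest], y[rest]),
                (Xm[fold], y[fold]),
                params=params,
                ncm=ncm,
                n_features=Xm.shape[1],
            )
        )
    return CcpModel(members=members, vocabulary=vocabulary, seed=seed)


def ccp_predict(ccp: CcpModel, x: FeatureVector | dict,
                confidence: float) -> PredictionInterval:
    """Aggregate member predictions: median midpoint, median width, then
    re-center the interval as midpoint +/- width/2."""
    mids = []
    widths = []
    for icp in ccp.members:
        iv = icp_predict(icp, x, confidence)
        mids.append(iv.midpoint)
        widths.append(iv.width)
    mid = float(np.median(mids))
    width = float(np.median(widths))
    return PredictionInterval.from_half_width(mid, width / 2.0, confidence)


def ccp_predict_many(ccp: CcpModel, X, confidence: float
                     ) -> list[PredictionInterval]:
    """Vectorized CCP prediction over a matrix or feature-vector list."""
    n_features = ccp.members[0].endpoint.n_features
    Xm = vectors_to_csr(X, n_features)
    n = Xm.shape[0]
    mids = np.empty((ccp.k, n))
    widths = np.empty((ccp.k, n))
    for m, icp in enumerate(ccp.members):
        y_hat = predict_many(icp.endpoint, Xm)
        alpha = alpha_at_confidence(icp.alphas, confidence)
        if icp.error_model is not None:
            mu = predict_many(icp.error_model, Xm)
            hw = np.array([
                half_width_from_alpha(alpha, float(m_i), icp.ncm)
                for m_i in mu
            ])
        else:
            hw = np.full(n, half_width_from_alpha(alpha, None, icp.ncm))
        mids[m] = y_hat
        widths[m] = 2.0 * hw
    mid = np.median(mids, axis=0)
    width = np.median(widths, axis=0)
    return [
        PredictionInterval.from_half_width(float(mid[i]), float(width[i]) / 2,
                                           confidence)
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Model archive: a tar file with a JSON manifest, the vocabulary TSV, one
# JSON per member model and one alpha array (text) per member.
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def _add_text(tar: tarfile.TarFile, name: str, text: str) -> None:
    data = text.encode()
    info = tarfile.TarInfo(name)
    info.size = len(data)
    info.mtime = 0
    tar.addfile(info, BytesIO(data))


def save_ccp(ccp: CcpModel, path: str | Path) -> None:
    """Persist a CCP archive (tar of JSON/TSV members)."""
    path = Path(path)
    with tarfile.open(path, "w") as tar:
        manifest = {
            "format_version": _FORMAT_VERSION,
            "k": ccp.k,
            "seed": ccp.seed,
            "heights": list(ccp.heights),
            "ncm": {
                "kind": ccp.ncm.kind,
                "beta": ccp.ncm.beta,
                "mu_floor": ccp.ncm.mu_floor,
                "err_floor": ccp.ncm.err_floor,
            },
            "has_vocabulary": ccp.vocabulary is not None,
        }
        _add_text(tar, "manifest.json", json.dumps(manifest, indent=1))
        if ccp.vocabulary is not None:
            import io as _io
            buf = _io.StringIO()
            buf.write("index\theight\tcount\tcanonical\n")
            for sig, idx in ccp.vocabulary.entries.items():
                buf.write(f"{idx}\t{sig.height}\t"
                          f"{ccp.vocabulary.support.get(sig, 0)}\t"
                          f"{sig.canonical}\n")
            _add_text(tar, "vocabulary.tsv", buf.getvalue())
        for i, icp in enumerate(ccp.members):
            member = {"endpoint": icp.endpoint.to_dict()}
            if icp.error_model is not None:
                member["error_model"] = icp.error_model.to_dict()
            _add_text(tar, f"member_{i:02d}.json", json.dumps(member))
            _add_text(
                tar, f"alphas_{i:02d}.txt",
                "\n".join(repr(float(a)) for a in icp.alphas) + "\n",
            )


def load_ccp(path: str | Path) -> CcpModel:
    """Load a CCP archive written by :func:`save_ccp`."""
    path = Path(path)
    with tarfile.open(path, "r") as tar:
        def read(name: str) -> str:
            fh = tar.extractfile(name)
            if fh is None:
                raise FileNotFoundError(f"{path}: missing member {name}")
            return fh.read().decode()

        manifest = json.loads(read("manifest.json"))
        if manifest["format_version"] != _FORMAT_VERSION:
            raise ConfigError(
                f"unsupported archive version {manifest['format_version']}"
            )
        ncm = NonconformityConfig(**manifest["ncm"])
        vocabulary = None
        if manifest.get("has_vocabulary"):
            from .signatures import AtomSignature

            entries: dict[AtomSignature, int] = {}
            support: dict[AtomSignature, int] = {}
            lines = read("vocabulary.tsv").splitlines()[1:]
            for line in lines:
                idx, height, count, canonical = line.split("\t")
                sig = AtomSignature(canonical, int(height))
                entries[sig] = int(idx)
                support[sig] = int(count)
            vocabulary = SignatureVocabulary(
                entries=entries,
                heights=frozenset(manifest["heights"]),
                min_count=1,
                support=support,
            )
        members = []
        for i in range(manifest["k"]):
            member = json.loads(read(f"member_{i:02d}.json"))
            alphas = np.array([
                float(v) for v in read(f"alphas_{i:02d}.txt").split()
            ])
            members.append(
                IcpModel(
                    endpoint=LinearModel.from_dict(member["endpoint"]),
                    error_model=(
                        LinearModel.from_dict(member["error_model"])
                        if "error_model" in member else None
                    ),
                    alphas=alphas,
                    ncm=ncm,
                )
            )
        return CcpModel(
            members=members,
            vocabulary=vocabulary,
            seed=manifest["seed"],
            heights=tuple(manifest["heights"]),
        )
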