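"""Fold-change-thresholded moderated differential expression.

A two-group comparison per feature with empirical-Bayes variance
moderation: the pooled sample variance s2 is shrunk toward a prior s02 with
prior degrees of freedom d0,

    s2_tilde = (d0 * s02 + d * s2) / (d0 + d),

where (d0, s02) are estimated by method of moments on log variances.  The
fold-change-thresholded p-value for threshold tau >= 0 is

    p = P(T >= (|logFC| - tau)/se) + P(T >= (|logFC| + tau)/se),

with T Student-t on d0 + d degrees of freedom; tau = 0 recovers the
ordinary two-sided moderated t-test.  Data are assumed to be on log2 scale
already, so the configured minimum fold change FC maps to tau = log2(FC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special, stats as sps

from .errors import ConfigError, DataError
from .io import MultiOmicDataset, RunConfig, logger
from .stats import bh_adjust

_VAR_FLOOR = 1e-10


@dataclass
class DEResult:
    feature: str
    contrast: str  # "<phenotype>_vs_<reference>"
    log_fc: float
    s2: float
    s2_tilde: float
    d0: float
    s02: float
    df_residual: float
    tau: float
    pvalue: float
    qvalue: float = float("nan")

    @property
    def direction(self) -> str:
        return "over" if self.log_fc > 0 else "under"


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (x > 0)."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def moderate_variances(s2: np.ndarray, d: float) -> tuple[float, float, np.ndarray]:
    """Estimate (d0, s02) and return the moderated variances.

    Method of moments on z = log(s2): under a scaled-F sampling model
    var(z) = trigamma(d/2) + trigamma(d0/2); when the observed variance of z
    does not exceed the sampling share, d0 is infinite and every moderated
    variance collapses to s02 (the geometric mean, so equal inputs are
    returned unchanged).
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 10:
        raise DataError("need >= 10 features for stable prior estimation")
    if np.any(s2 < 0):
        raise DataError("variances must be non-negative")
    if np.any(s2 < _VAR_FLOOR):
        logger.warning("%d zero variances floored at %g", int((s2 < _VAR_FLOOR).sum()), _VAR_FLOOR)
        s2 = np.maximum(s2, _VAR_FLOOR)
    z = np.log(s2)
    evar = float(np.var(z, ddof=1)) - float(special.polygamma(1, d / 2.0))
    if evar <= 0.0:
        d0 = math.inf
        s02 = float(np.exp(np.mean(z)))
        return d0, s02, np.full_like(s2, s02)
    d0 = 2.0 * _trigamma_inverse(evar)
    s02 = float(
        np.exp(
            np.mean(z)
            - special.digamma(d / 2.0)
            + special.digamma(d0 / 2.0)
            + math.log(d / d0)
        )
    )
    return d0, s02, moderated_variance(s2, d, d0, s02)


def moderated_variance(s2, d: float, d0: float, s02: float) -> np.ndarray:
    """Shrinkage formula s2_tilde = (d0*s02 + d*s2) / (d0 + d)."""
    s2 = np.asarray(s2, dtype=float)
    if math.isinf(d0):
        return np.full_like(s2, s02)
    return (d0 * s02 + d * s2) / (d0 + d)


def treat_test(log_fc, se, df: float, tau: float) -> np.ndarray:
    """Fold-change-thresholded t-test p-values (vectorized).

    ``se`` is the standard error of the log fold change built from the
    moderated variance; ``df`` the total (residual + prior) degrees of
    freedom.
    """
    if tau < 0:
        raise ConfigError("tau must be >= 0")
    log_fc = np.atleast_1d(np.asarray(log_fc, dtype=float))
    se = np.broadcast_to(np.asarray(se, dtype=float), log_fc.shape)
    if np.any(se <= 0):
        raise DataError("standard errors must be positive")
    t_right = (np.abs(log_fc) - tau) / se
    t_left = (np.abs(log_fc) + tau) / se
    p = sps.t.sf(t_right, df) + sps.t.sf(t_left, df)
    return np.minimum(p, 1.0)


def de_per_phenotype(
    dataset: MultiOmicDataset,
    features: Sequence[str],
    config: RunConfig,
) -> list[DEResult]:
    """Contrast each tumor phenotype against the normal phenotype.

    Pooled two-group variances are moderated across the supplied features;
    BH adjustment is applied per contrast.
    """
    rows = [dataset.feature_row(f) for f in features]  # raises for missing
    normal = config.normal_phenotype
    if normal not in dataset.phenotypes:
        raise DataError(f"normal phenotype {normal!r} not present in dataset")
    tau = math.log2(config.fold_change_threshold)
    norm_idx = dataset.samples_of(normal)
    results: list[DEResult] = []
    for ph in dataset.phenotypes:
        if ph == normal:
            continue
        ph_idx = dataset.samples_of(ph)
        a = dataset.values[np.ix_(rows, ph_idx)]
        b = dataset.values[np.ix_(rows, norm_idx)]
        n1, n2 = a.shape[1], b.shape[1]
        if n1 < 2 or n2 < 2:
            logger.warning("contrast %s vs %s skipped: too few samples", ph, normal)
            continue
        log_fc = a.mean(axis=1) - b.mean(axis=1)
        d = n1 + n2 - 2
        s2 = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / d
        d0, s02, s2_tilde = moderate_variances(s2, d)
        se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
        df_total = d + d0 if not math.isinf(d0) else math.inf
        p = treat_test(log_fc, se, df_total, tau)
        q = bh_adjust(p)
        contrast = f"{ph}_vs_{normal}"
        for i, f in enumerate(features):
            results.append(
                DEResult(
                    feature=f,
                    contrast=contrast,
                    log_fc=float(log_fc[i]),
                    s2=float(s2[i]),
                    s2_tilde=float(s2_tilde[i]),
                    d0=float(d0),
                    s02=float(s02),
                    df_residual=float(d),
                    tau=float(tau),
                    pvalue=float(p[i]),
                    qvalue=float(q[i]),
                )
            )
    return results


def de_frame(results: Sequence[DEResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "contrast": r.contrast,
                "logFC": r.log_fc,
                "direction": r.direction,
                "s2": r.s2,
                "s2_tilde": r.s2_tilde,
                "d0": r.d0,
                "s02": r.s02,
                "tau": r.tau,
                "p": r.pvalue,
                "q": r.qvalue,
            }
            for r in results
        ]
    )
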