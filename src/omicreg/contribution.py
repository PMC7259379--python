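"""Per-omic contribution to prediction via coefficient masking.

Fitted coefficients are never refit: an omic's contribution is measured by
zeroing every coefficient outside that omic in the already fitted model and
re-scoring the held-out samples.  The resulting RMSE distributions are then
compared with two-sample Kolmogorov-Smirnov tests, Benjamini-Hochberg
adjusted within each test family.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .fitting import GeneModel, SplitPlan, standardize
from .io import OMICS, MultiOmicDataset, RunConfig, logger
from .stats import bh_adjust, ks_two_sample

MASK_ALL = "all"


@dataclass
class OmicRMSE:
    gene: str
    phenotype: str
    rmse_full: float
    rmse_by_omic: dict[str, float]


@dataclass
class ComparisonResult:
    family: str  # within_phenotype | across_phenotype | pooled
    label_a: str
    label_b: str
    scope: str  # phenotype or omic the pair is nested in ("" for pooled)
    statistic: float
    pvalue: float
    qvalue: float = float("nan")


def masked_predict(
    model: GeneModel,
    test_frame: pd.DataFrame,
    omic: str,
    omic_of: Mapping[str, str],
) -> np.ndarray:
    """Prediction keeping only coefficients of one omic (or ``"all"``).

    ``test_frame`` is a standardized features x samples frame indexed by
    feature id.  The intercept is retained in every masked prediction.
    """
    pred = np.full(test_frame.shape[1], model.intercept, dtype=float)
    for fid, beta in model.coef.items():
        if omic == MASK_ALL or omic_of[fid] == omic:
            pred += beta * test_frame.loc[fid].to_numpy()
    return pred


def masked_rmse(
    model: GeneModel,
    test_frame: pd.DataFrame,
    y_test: np.ndarray,
    omic: str,
    omic_of: Mapping[str, str],
) -> float:
    """RMSE of the omic-masked prediction on held-out samples."""
    if omic != MASK_ALL and omic not in OMICS:
        raise DataError(f"unknown omic {omic!r}")
    if omic != MASK_ALL and not any(omic_of[f] == omic for f in model.coef):
        logger.info(
            "model (%s, %s): no %s features selected; intercept-only prediction",
            model.gene, model.phenotype, omic,
        )
    pred = masked_predict(model, test_frame, omic, omic_of)
    return float(np.sqrt(np.mean((np.asarray(y_test, float) - pred) ** 2)))


def decompose(
    models: Sequence[GeneModel],
    dataset: MultiOmicDataset,
    split: SplitPlan,
    config: RunConfig,
) -> list[OmicRMSE]:
    """Masked RMSE per omic for every fitted model on its test split."""
    omic_of = dict(zip(dataset.feature_ids, dataset.feature_omic))
    sample_pos = {s: i for i, s in enumerate(dataset.sample_ids)}
    results: list[OmicRMSE] = []
    by_ph: dict[str, list[GeneModel]] = {}
    for m in models:
        by_ph.setdefault(m.phenotype, []).append(m)
    for ph, ph_models in by_ph.items():
        tr_idx = [sample_pos[s] for s in split.train[ph]]
        te_idx = [sample_pos[s] for s in split.test[ph]]
        _, test_s, _ = standardize(dataset.values[:, tr_idx], dataset.values[:, te_idx])
        test_frame = pd.DataFrame(test_s, index=dataset.feature_ids)
        for m in ph_models:
            y_test = test_frame.loc[m.gene].to_numpy()
            full = masked_rmse(m, test_frame, y_test, MASK_ALL, omic_of)
            per_omic = {o: masked_rmse(m, test_frame, y_test, o, omic_of) for o in OMICS}
            results.append(OmicRMSE(gene=m.gene, phenotype=ph, rmse_full=full, rmse_by_omic=per_omic))
    return results


def results_frame(results: Sequence[OmicRMSE]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"gene": r.gene, "phenotype": r.phenotype, "full": r.rmse_full}
        row.update(r.rmse_by_omic)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_rmse_distributions(
    results: Sequence[OmicRMSE],
    grouping: str = "per_phenotype",
    method: str = "asymp",
) -> list[ComparisonResult]:
    """KS comparisons of masked-RMSE distributions.

    ``per_phenotype``: every pair of omic columns (including the full model)
    within each phenotype, plus each omic compared across phenotype pairs.
    ``pooled``: omic-column pairs with phenotypes mixed.  BH adjustment is
    applied separately per family.
    """
    if grouping not in ("per_phenotype", "pooled"):
        raise DataError(f"unknown grouping {grouping!r}")
    frame = results_frame(results)
    columns = ["full", *OMICS]
    out: list[ComparisonResult] = []

    def add(family: str, a_lab: str, b_lab: str, scope: str, a: np.ndarray, b: np.ndarray) -> None:
        if len(a) < 2 or len(b) < 2:
            logger.warning("comparison %s|%s vs %s skipped: <2 values", scope, a_lab, b_lab)
            return
        d, p = ks_two_sample(a, b, method=method)
        out.append(ComparisonResult(family, a_lab, b_lab, scope, d, p))

    if grouping == "pooled":
        for a_col, b_col in combinations(columns, 2):
            add("pooled", a_col, b_col, "", frame[a_col].to_numpy(), frame[b_col].to_numpy())
    else:
        for ph, sub in frame.groupby("phenotype", sort=True):
            for a_col, b_col in combinations(columns, 2):
                add("within_phenotype", a_col, b_col, str(ph),
                    sub[a_col].to_numpy(), sub[b_col].to_numpy())
        phenos = sorted(frame["phenotype"].unique())
        for col in columns:
            for pa, pb in combinations(phenos, 2):
                add("across_phenotype", pa, pb, col,
                    frame.loc[frame["phenotype"] == pa, col].to_numpy(),
                    frame.loc[frame["phenotype"] == pb, col].to_numpy())

    for family in {c.family for c in out}:
        members = [c for c in out if c.family == family]
        qs = bh_adjust([c.pvalue for c in members])
        for c, q in zip(members, qs):
            c.qvalue = float(q)
    return out


def comparisons_frame(comparisons: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "family": c.family,
                "scope": c.scope,
                "a": c.label_a,
                "b": c.label_b,
                "D": c.statistic,
                "p": c.pvalue,
                "q": c.qvalue,
            }
            for c in comparisons
        ]
    )
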