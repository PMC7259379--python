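"""Enrichment of selected predictors for known regulator->target links.

The universe of each test is constrained to measured features of the
regulator class that carry at least one record in the reference table; the
alternative is over-selection of known regulators of the very gene a
predictor was selected for.  A composition test additionally asks whether
the omic make-up of the selected predictors can be explained by the omic
make-up of the input feature space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import DataError
from .fitting import GeneModel
from .io import OMICS, KnownLinkDB, MultiOmicDataset, logger
from .stats import bh_adjust


@dataclass
class EnrichmentTest:
    scope: str
    table: tuple[int, int, int, int]  # (a, b, c, d)
    odds_ratio: float
    alternative: str
    pvalue: float
    qvalue: float = float("nan")

    @property
    def universe_size(self) -> int:
        return sum(self.table)


@dataclass
class Chi2Result:
    statistic: float
    pvalue: float
    dof: int
    observed: dict[str, int]
    expected: dict[str, float]


def fisher_exact(table, alternative: str = "greater") -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table given as ((a, b), (c, d)).

    Returns the sample odds ratio ad/bc (``inf`` when bc == 0 and ad > 0)
    and the conditional hypergeometric p-value.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise DataError("table must be 2x2")
    if np.any(arr < 0):
        raise DataError("table counts must be non-negative")
    if not np.all(arr == np.floor(arr)):
        raise DataError("table counts must be integers")
    arr = arr.astype(int)
    res = sps.fisher_exact(arr, alternative=alternative)
    a, b = arr[0]
    c, d = arr[1]
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
        logger.info("degenerate odds ratio for table %s", arr.tolist())
    else:
        odds = a * d / (b * c)
    return float(odds), float(res.pvalue)


def known_link_test(
    models: Sequence[GeneModel],
    db: KnownLinkDB,
    dataset: MultiOmicDataset,
) -> list[EnrichmentTest]:
    """Per (regulator class, phenotype, gene) Fisher tests, BH-adjusted
    across genes within each (class, phenotype) family.

    For class ``c`` and gene ``g``: universe = measured class-``c`` features
    with any record in ``db``; successes = known regulators of ``g``;
    draws = selected class-``c`` features of the (g, phenotype) model lying
    in the universe; ``a`` = selected known regulators of ``g``.
    """
    results: list[EnrichmentTest] = []
    db_regulators = db.regulators()
    universes = {
        omic: {f for f in dataset.features_of(omic) if f in db_regulators}
        for omic in OMICS
    }
    phenotypes = sorted({m.phenotype for m in models})
    for omic in OMICS:
        universe = universes[omic]
        if not universe:
            logger.warning("no measured %s features with known targets; tests skipped", omic)
            continue
        for ph in phenotypes:
            family: list[EnrichmentTest] = []
            for m in (m for m in models if m.phenotype == ph):
                known = db.regulators_of(m.gene) & universe
                selected = {f for f in m.selected_by_omic.get(omic, [])} & universe
                a = len(selected & known)
                b = len(selected) - a
                c = len(known) - a
                d = len(universe) - a - b - c
                odds, p = fisher_exact(((a, b), (c, d)), alternative="greater")
                family.append(
                    EnrichmentTest(
                        scope=f"{omic}:{ph}:{m.gene}",
                        table=(a, b, c, d),
                        odds_ratio=odds,
                        alternative="greater",
                        pvalue=p,
                    )
                )
            qs = bh_adjust([t.pvalue for t in family])
            for t, q in zip(family, qs):
                t.qvalue = float(q)
            results.extend(family)
    return results


def composition_test(
    models: Sequence[GeneModel],
    dataset: MultiOmicDataset,
) -> tuple[dict[str, Chi2Result], dict[str, list[EnrichmentTest]]]:
    """Selected-omic composition vs input composition, per phenotype.

    Returns a goodness-of-fit chi-square (no continuity correction,
    df = #omics - 1) plus, per omic, 2x2 Fisher tests with both one-sided
    alternatives (over- and under-representation).
    """
    input_counts = {omic: len(dataset.features_of(omic)) for omic in OMICS}
    present = [o for o in OMICS if input_counts[o] > 0]
    total_input = sum(input_counts.values())
    chi2: dict[str, Chi2Result] = {}
    fishers: dict[str, list[EnrichmentTest]] = {}
    by_ph: dict[str, list[GeneModel]] = {}
    for m in models:
        by_ph.setdefault(m.phenotype, []).append(m)
    for ph, ph_models in sorted(by_ph.items()):
        selected: dict[str, set[str]] = {omic: set() for omic in OMICS}
        for m in ph_models:
            for omic, feats in m.selected_by_omic.items():
                selected[omic].update(feats)
        sel_counts = {omic: len(selected[omic]) for omic in OMICS}
        total_sel = sum(sel_counts.values())
        if total_sel == 0:
            logger.warning("phenotype %s has no selections; composition test skipped", ph)
            continue
        observed = np.array([sel_counts[o] for o in present], dtype=float)
        expected = np.array([total_sel * input_counts[o] / total_input for o in present])
        stat, p = sps.chisquare(observed, f_exp=expected)
        chi2[ph] = Chi2Result(
            statistic=float(stat),
            pvalue=float(p),
            dof=len(present) - 1,
            observed={o: int(sel_counts[o]) for o in present},
            expected={o: float(e) for o, e in zip(present, expected)},
        )
        tests: list[EnrichmentTest] = []
        for omic in present:
            a = sel_counts[omic]
            b = total_sel - a
            c = input_counts[omic] - a
            d = (total_input - input_counts[omic]) - b
            for alternative in ("greater", "less"):
                odds, pv = fisher_exact(((a, b), (c, d)), alternative=alternative)
                tests.append(
                    EnrichmentTest(
                        scope=f"composition:{ph}:{omic}",
                        table=(a, b, c, d),
                        odds_ratio=odds,
                        alternative=alternative,
                        pvalue=pv,
                    )
                )
        fishers[ph] = tests
    return chi2, fishers


def enrichment_frame(tests: Sequence[EnrichmentTest]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "scope": t.scope,
                "a": t.table[0],
                "b": t.table[1],
                "c": t.table[2],
                "d": t.table[3],
                "odds_ratio": t.odds_ratio,
                "alternative": t.alternative,
                "p": t.pvalue,
                "q": t.qvalue,
            }
            for t in tests
        ]
    )
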