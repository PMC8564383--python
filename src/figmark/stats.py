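"""Population tallies, segregation statistics and the 2^-ddCt helper.

The F1 sex ratio is reported as "1:x" with x = males/females rounded to
two significant figures (trailing zeros stripped), the formatting that
reproduces both published ratios (1:1.2 and 1:0.73).  The chi-square
goodness-of-fit to 1:1 uses df=1 with no continuity correction by
default (Yates optional).
"""
from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import PopulationSummary, SexCall


def format_ratio(n_female: int, n_male: int) -> str:
    if n_female == 0:
        return "1:inf"
    return "1:" + f"{n_male / n_female:.2g}"


def chi_square_1to1(n_female: int, n_male: int, yates: bool = False) -> Tuple[float, float]:
    """Goodness of fit of observed sex counts to the 1:1 Mendelian
    expectation of the ga/ga x GA/ga cross (df = 1)."""
    n = n_female + n_male
    if n <= 0:
        raise ValueError("empty population")
    exp = n / 2.0
    if yates:
        chi2 = sum((abs(o - exp) - 0.5) ** 2 / exp for o in (n_female, n_male))
    else:
        chi2 = sum((o - exp) ** 2 / exp for o in (n_female, n_male))
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def tally_population(
    calls: Sequence[SexCall], population: str = "", yates: bool = False
) -> PopulationSummary:
    counts = {"female": 0, "male": 0, "ambiguous": 0, "failed": 0}
    for c in calls:
        counts[c.call] += 1
    chi2, p = (
        chi_square_1to1(counts["female"], counts["male"], yates=yates)
        if counts["female"] + counts["male"] > 0
        else (float("nan"), float("nan"))
    )
    return PopulationSummary(
        population=population or (calls[0].marker if calls else ""),
        n_female=counts["female"],
        n_male=counts["male"],
        n_ambiguous=counts["ambiguous"],
        n_failed=counts["failed"],
        ratio_text=format_ratio(counts["female"], counts["male"]),
        chi2=chi2,
        p_value=p,
    )


def concordance(
    calls_a: Sequence[SexCall], calls_b: Sequence[SexCall]
) -> Tuple[float, List[str]]:
    """Fraction of samples on which two markers agree, over pairs where
    neither call failed, plus the list of discordant sample ids."""
    a = {c.sample_id: c.call for c in calls_a}
    b = {c.sample_id: c.call for c in calls_b}
    if a.keys() != b.keys():
        raise ValueError("call sets cover different samples")
    pairs = [
        (sid, a[sid], b[sid])
        for sid in a
        if a[sid] != "failed" and b[sid] != "failed"
    ]
    if not pairs:
        return float("nan"), []
    discordant = sorted(sid for sid, ca, cb in pairs if ca != cb)
    return 1.0 - len(discordant) / len(pairs), discordant


def relative_expression(
    table: pd.DataFrame,
    reference_gene: str,
    calibrator_sample: str,
    sample_col: str = "sample",
    gene_col: str = "gene",
    ct_col: str = "ct",
) -> pd.DataFrame:
    """Fold change by the 2^-ddCt method.

    dCt = Ct(gene) - Ct(reference) per sample; ddCt subtracts the
    calibrator sample's dCt; the fold change is 2**(-ddCt), so the
    calibrator itself reports 1.0 for every gene.
    """
    df = table.copy()
    ref = df[df[gene_col] == reference_gene].set_index(sample_col)[ct_col]
    missing = set(df[sample_col]) - set(ref.index)
    if missing:
        raise ValueError(f"reference gene {reference_gene!r} missing for samples {sorted(missing)}")
    df = df[df[gene_col] != reference_gene].copy()
    df["dct"] = df[ct_col].to_numpy() - ref.loc[df[sample_col]].to_numpy()
    cal = df[df[sample_col] == calibrator_sample].set_index(gene_col)["dct"]
    if cal.empty:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not in table")
    df["ddct"] = df["dct"].to_numpy() - cal.loc[df[gene_col]].to_numpy()
    df["fold_change"] = 2.0 ** (-df["ddct"])
    return df[[sample_col, gene_col, "fold_change"]].reset_index(drop=True)


def null_rejection_rate(
    n: int, n_sims: int = 2000, alpha: float = 0.05, seed: int = 0
) -> float:
    """Monte-Carlo type-I error of the 1:1 test on Bernoulli(0.5)
    populations of size n (vectorised; used to check calibration)."""
    rng = np.random.default_rng(seed)
    males = rng.binomial(n, 0.5, size=n_sims)
    chi2 = (2.0 * males - n) ** 2 / n
    crit = sps.chi2.ppf(1.0 - alpha, df=1)
    return float(np.mean(chi2 > crit))
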