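"""Psychometric test-based MCI classification (MCI-TB).

At each wave, the sample is stratified by education (0–12 vs 13+ years) and a
subject is labelled MCI-TB when they score more than 1.5 SD below the stratum
mean on at least ``min_tests_impaired`` of four tests: perceptual speed
(symbol-digit), episodic memory (immediate recall), working memory (digit
span backward) and vocabulary (spot-the-word). The stringent sensitivity
variant requires impairment on two or more tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TESTS = ("perceptual_speed", "episodic_memory", "working_memory", "vocabulary")

#: education strata: (label, predicate on years of education)
EDUCATION_STRATA = ("0-12", "13+")
SD_MULTIPLIER = 1.5


class NormsError(ValueError):
    pass


def education_stratum(years: float) -> str:
    if years is None or (isinstance(years, float) and np.isnan(years)):
        raise NormsError("education is missing; cannot assign a stratum")
    return "13+" if years >= 13 else "0-12"


@dataclass
class StratumNorms:
    """Per-stratum, per-test mean, SD and impairment threshold (mean−1.5·SD)."""

    table: pd.DataFrame  # index: (stratum, test); columns: mean, sd, threshold

    def threshold(self, stratum: str, test: str) -> float:
        return float(self.table.loc[(stratum, test), "threshold"])


def compute_norms(records: pd.DataFrame, sd_multiplier: float = SD_MULTIPLIER
                  ) -> StratumNorms:
    """Norms from one wave's records (columns: education_years + the 4 tests).

    Mean and SD (n−1) are taken over the full available sample in each
    education stratum; the impairment threshold is mean − 1.5·SD. Degenerate
    strata (fewer than 2 subjects, or zero SD on any test) raise.
    """
    strata = records["education_years"].map(education_stratum)
    rows = []
    for stratum in EDUCATION_STRATA:
        sub = records[strata == stratum]
        if len(sub) == 0:
            raise NormsError(f"education stratum {stratum!r} is empty")
        if len(sub) < 2:
            raise NormsError(f"education stratum {stratum!r} has fewer than 2 subjects")
        for test in TESTS:
            x = sub[test].to_numpy(dtype=float)
            if np.isnan(x).any():
                raise NormsError(f"missing {test} scores in stratum {stratum!r}")
            mu, sd = x.mean(), x.std(ddof=1)
            if sd == 0:
                raise NormsError(f"zero SD for {test} in stratum {stratum!r}")
            rows.append({"stratum": stratum, "test": test, "mean": mu, "sd": sd,
                         "threshold": mu - sd_multiplier * sd})
    table = pd.DataFrame(rows).set_index(["stratum", "test"])
    return StratumNorms(table)


def classify_record(record, norms: StratumNorms, min_tests_impaired: int = 1) -> str:
    """Classify one subject-wave as ``CN`` or ``MCI_TB``.

    A test counts as impaired when the score is strictly below the stratum
    threshold (a score exactly at mean−1.5·SD is not impaired).
    """
    if min_tests_impaired not in (1, 2):
        raise ValueError("min_tests_impaired must be 1 or 2")
    stratum = education_stratum(record["education_years"])
    n_impaired = sum(
        float(record[test]) < norms.threshold(stratum, test) for test in TESTS)
    return "MCI_TB" if n_impaired >= min_tests_impaired else "CN"


def classify_wave(records: pd.DataFrame, min_tests_impaired: int = 1,
                  norms: StratumNorms | None = None) -> pd.Series:
    """Classify every record at one wave; norms default to that wave's sample."""
    if norms is None:
        norms = compute_norms(records)
    return records.apply(
        lambda r: classify_record(r, norms, min_tests_impaired), axis=1)


def classify_panel(records: pd.DataFrame, min_tests_impaired: int = 1,
                   baseline_norms: bool = False) -> pd.Series:
    """Classify a multi-wave table (needs a ``wave`` column).

    Norms are recomputed on each wave's available sample by default; with
    ``baseline_norms`` the first wave's norms are applied throughout.
    """
    out = pd.Series(index=records.index, dtype=object)
    norms = None
    for wave in sorted(records["wave"].unique()):
        sub = records[records["wave"] == wave]
        if norms is None or not baseline_norms:
            norms = compute_norms(sub)
        out.loc[sub.index] = classify_wave(sub, min_tests_impaired, norms)
    return out
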