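"""Long-format cohort panel container, validation and exclusion rules.

A cohort panel holds one row per subject-wave with the subject's age at the
interview, the cognitive state assigned at that wave, and any baseline
covariates carried along for modelling. States observed at discrete waves are
interval-censored: the panel records where a subject *was* at each visit, not
when transitions happened.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical state labels (MCI_TB is the psychometric test-based MCI state)
CN = "CN"
MCI = "MCI"
MCI_TB = "MCI_TB"
DEMENTIA = "DEMENTIA"
DEATH = "DEATH"
CENSORED = "CENSORED"

STATES = (CN, MCI, MCI_TB, DEMENTIA, DEATH, CENSORED)
TERMINAL_STATES = frozenset({DEATH, CENSORED})

REQUIRED_COLUMNS = ("subject_id", "wave", "age", "state")


class PanelSchemaError(ValueError):
    """A required column is absent or mis-typed."""


class PanelValidationError(ValueError):
    """Panel rows violate a structural invariant (named subject in message)."""


@dataclass
class CohortPanel:
    """Validated long-format panel: one row per subject-wave.

    Parameters
    ----------
    data : pandas.DataFrame
        Must contain ``subject_id``, ``wave``, ``age``, ``state``; any further
        columns are treated as covariates. An optional ``death_age`` column
        gives the exactly-observed age at death for DEATH rows.
    """

    data: pd.DataFrame
    covariate_names: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise PanelSchemaError(f"missing required column(s): {missing}")
        # wave order defines the observation sequence; age monotonicity is then
        # a checkable invariant rather than something sorting would enforce
        df = self.data.sort_values(["subject_id", "wave"], kind="stable").reset_index(drop=True)
        object.__setattr__(self, "data", df)
        extras = [c for c in df.columns if c not in REQUIRED_COLUMNS and c != "death_age"]
        object.__setattr__(self, "covariate_names", tuple(extras))
        self._validate()

    # -- invariants ------------------------------------------------------
    def _validate(self) -> None:
        df = self.data
        bad_state = set(df["state"].dropna()) - set(STATES)
        if bad_state:
            raise PanelValidationError(f"unknown state label(s): {sorted(bad_state)}")
        for sid, grp in df.groupby("subject_id", sort=False):
            ages = grp["age"].to_numpy(dtype=float)
            if np.any(np.diff(ages) <= 0):
                raise PanelValidationError(
                    f"ages not strictly increasing for subject {sid!r}"
                )
            states = grp["state"].tolist()
            for k, st in enumerate(states[:-1]):
                if st in TERMINAL_STATES:
                    raise PanelValidationError(
                        f"record after terminal state {st} for subject {sid!r}"
                    )
            if any(pd.isna(s) for s in states):
                raise PanelValidationError(
                    f"undefined state for subject {sid!r}"
                )

    # -- convenience -----------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    @property
    def subject_ids(self) -> list:
        return list(self.data["subject_id"].unique())

    def subject(self, sid) -> pd.DataFrame:
        return self.data[self.data["subject_id"] == sid]

    def observation_counts(self) -> pd.Series:
        return self.data.groupby("subject_id", sort=False).size()

    def missingness_report(self, variables: list[str] | None = None) -> "MissingnessReport":
        cols = list(variables) if variables is not None else list(self.covariate_names)
        n = len(self.data)
        rows = []
        for c in cols:
            miss = int(self.data[c].isna().sum())
            rows.append({"variable": c, "n_missing": miss, "fraction": miss / n if n else 0.0})
        return MissingnessReport(pd.DataFrame(rows))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class MissingnessReport:
    """Per-variable missing counts and fractions."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        fr = self.table["fraction"]
        if len(fr) and ((fr < 0).any() or (fr > 1).any()):
            raise ValueError("missingness fractions must lie in [0, 1]")

    def fraction(self, variable: str) -> float:
        row = self.table[self.table["variable"] == variable]
        if row.empty:
            raise KeyError(variable)
        return float(row["fraction"].iloc[0])


def read_panel(path, schema: dict[str, str] | None = None,
               state_labels: dict[str, str] | None = None,
               sep: str = ",") -> CohortPanel:
    """Read a delimited panel table into a validated :class:`CohortPanel`.

    Parameters
    ----------
    path : str or file-like
        CSV/TSV with a header row.
    schema : dict, optional
        Maps canonical role names (``subject_id``, ``wave``, ``age``,
        ``state``, ``death_age``) to the file's column names. Unmapped extra
        columns ride along as covariates.
    state_labels : dict, optional
        Maps the file's state labels to the canonical ones (``CN``, ``MCI``,
        ``DEMENTIA``, ``DEATH``, ``CENSORED``).
    """
    df = pd.read_csv(path, sep=sep)
    if schema:
        rename = {src: role for role, src in schema.items() if src in df.columns}
        missing = [src for src in schema.values() if src not in df.columns]
        if missing:
            raise PanelSchemaError(f"column(s) {missing} mapped in schema but absent from file")
        df = df.rename(columns=rename)
    if state_labels:
        df["state"] = df["state"].map(lambda s: state_labels.get(s, s))
    return CohortPanel(df)


def apply_exclusions(panel: CohortPanel, genotyped: set | None = None
                     ) -> tuple[CohortPanel, dict[str, int]]:
    """Apply the analysis-sample exclusion rules.

    Subjects are dropped if (in this priority order, each subject counted once
    under the first rule it fails):

    1. ``no_genotype`` — subject id not in ``genotyped`` (skipped when
       ``genotyped`` is None);
    2. ``single_obs`` — fewer than two panel observations, so no transition
       is ever observed.

    Returns the reduced panel and a count per exclusion reason.
    """
    counts = {"no_genotype": 0, "single_obs": 0}
    keep = []
    obs = panel.observation_counts()
    for sid in panel.subject_ids:
        if genotyped is not None and sid not in genotyped:
            counts["no_genotype"] += 1
            continue
        if obs[sid] < 2:
            counts["single_obs"] += 1
            continue
        keep.append(sid)
    if not keep:
        raise PanelValidationError("no subjects remain after exclusions")
    out = CohortPanel(panel.data[panel.data["subject_id"].isin(keep)].copy())
    return out, counts
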