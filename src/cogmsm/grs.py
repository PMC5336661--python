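"""Explained-variance-weighted genetic risk score (EV-GRS).

Each SNP contributes ``ln(OR) * sqrt(2*MAF*(1-MAF)) * G`` where ``OR`` is the
published disease odds ratio for the risk allele, ``MAF`` the minor allele
frequency in a reference population, and ``G`` in {0,1,2} the subject's
risk-allele dosage. The weight is the per-allele log odds scaled by the
standard deviation of the allele count under Hardy–Weinberg equilibrium, so
SNPs that explain more population variance weigh more. The summed score is
standardised to a z-score over the analysis sample; downstream hazard ratios
are reported per SD of the score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class GrsError(ValueError):
    pass


@dataclass
class SnpWeightTable:
    """Per-SNP risk allele, odds ratio and minor allele frequency.

    Backed by a DataFrame with columns ``snp_id``, ``risk_allele``, ``or``,
    ``maf``; identifiers must be unique, ORs positive and MAFs in (0, 0.5].
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"snp_id", "risk_allele", "or", "maf"}
        missing = req - set(self.table.columns)
        if missing:
            raise GrsError(f"weight table lacks column(s) {sorted(missing)}")
        if self.table["snp_id"].duplicated().any():
            raise GrsError("duplicate SNP identifiers in weight table")
        if (self.table["or"] <= 0).any():
            raise GrsError("odds ratios must be positive")
        maf = self.table["maf"]
        if ((maf <= 0) | (maf > 0.5)).any():
            raise GrsError("MAFs must lie in (0, 0.5]")

    @classmethod
    def from_csv(cls, path) -> "SnpWeightTable":
        return cls(pd.read_csv(path))

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    def weights(self) -> pd.Series:
        """Per-SNP weight ln(OR)·sqrt(2·MAF·(1−MAF)), indexed by snp_id."""
        t = self.table
        w = np.log(t["or"].to_numpy()) * np.sqrt(
            2.0 * t["maf"].to_numpy() * (1.0 - t["maf"].to_numpy()))
        return pd.Series(w, index=t["snp_id"].to_numpy(), name="weight")


def ev_grs(weights: SnpWeightTable, dosages: dict[str, int]) -> float:
    """Raw EV-GRS for one subject from per-SNP risk-allele dosages.

    Every SNP in ``dosages`` must appear in the weight table and carry a
    non-missing dosage in {0, 1, 2}; subjects with missing genotypes are
    excluded upstream rather than imputed.
    """
    w = weights.weights()
    total = 0.0
    for snp, g in dosages.items():
        if snp not in w.index:
            raise GrsError(f"unknown SNP {snp!r}")
        if g is None or (isinstance(g, float) and np.isnan(g)):
            raise GrsError(f"missing dosage for SNP {snp!r}")
        if g not in (0, 1, 2):
            raise GrsError(f"dosage for {snp!r} must be 0, 1 or 2, got {g!r}")
        total += float(w[snp]) * g
    return total


def ev_grs_matrix(weights: SnpWeightTable, genotypes: pd.DataFrame) -> pd.Series:
    """Raw EV-GRS for every subject in a wide dosage table.

    ``genotypes``: rows = subjects (index = subject id), columns = SNP ids,
    values = risk-allele dosages in {0,1,2}. Any missing cell raises; the
    exclusion of non-genotyped subjects is an upstream preprocessing step.
    """
    w = weights.weights()
    unknown = set(genotypes.columns) - set(w.index)
    if unknown:
        raise GrsError(f"unknown SNP(s) in genotype table: {sorted(unknown)}")
    G = genotypes.to_numpy(dtype=float)
    if np.isnan(G).any():
        bad = genotypes.index[np.isnan(G).any(axis=1)].tolist()
        raise GrsError(f"missing dosages for subject(s) {bad[:5]} — exclude upstream")
    if not np.isin(G, (0.0, 1.0, 2.0)).all():
        raise GrsError("dosages must be 0, 1 or 2")
    scores = G @ w.loc[list(genotypes.columns)].to_numpy()
    return pd.Series(scores, index=genotypes.index, name="ev_grs")


def dosages_from_vcf(path, weights: SnpWeightTable) -> pd.DataFrame:
    """Risk-allele dosage table from a diploid biallelic VCF.

    Variants are matched on the VCF ID field against the weight table; the
    dosage counts copies of the table's risk allele (REF or ALT), so an allele
    mismatch with the table raises. Missing genotypes become NaN for upstream
    exclusion.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    wanted = {r.snp_id: r.risk_allele for r in weights.table.itertuples()}
    cols: dict[str, np.ndarray] = {}
    for var in vcf:
        if var.ID not in wanted or len(var.ALT) != 1:
            continue
        risk = wanted[var.ID]
        if risk == var.ALT[0]:
            alt_is_risk = True
        elif risk == var.REF:
            alt_is_risk = False
        else:
            raise GrsError(
                f"risk allele {risk!r} for {var.ID} matches neither REF nor ALT")
        g = np.asarray(var.genotypes, dtype=object)
        dos = np.full(len(samples), np.nan)
        for i, call in enumerate(g):
            a, b = call[0], call[1]
            if a < 0 or b < 0:
                continue
            alt_count = int(a == 1) + int(b == 1)
            dos[i] = alt_count if alt_is_risk else 2 - alt_count
        cols[var.ID] = dos
    return pd.DataFrame(cols, index=samples)


def zscore(scores) -> np.ndarray:
    """Standardise raw scores over the analysis sample (n−1 denominator SD)."""
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise GrsError("need at least 2 scores to standardise")
    sd = x.std(ddof=1)
    if sd == 0:
        raise GrsError("zero variance: cannot standardise a constant score")
    return (x - x.mean()) / sd
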