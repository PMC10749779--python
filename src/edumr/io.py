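"""Delimited readers/writers for the pipeline's external formats.

GWAS summary statistics use a PLINK-style layout (SNP, A1, A2, BETA, SE, P,
EAF; tab-delimited with a header, A1 = effect allele).  Cohorts and dosage
matrices are plain delimited tables with a header row.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError
from .simulate import GenotypePanel, GwasSummaryRecord

GWAS_COLUMNS = ["SNP", "A1", "A2", "BETA", "SE", "P", "EAF"]


def write_gwas(records: Sequence[GwasSummaryRecord], path) -> None:
    df = pd.DataFrame(
        {
            "SNP": [r.snp_id for r in records],
            "A1": [r.effect_allele for r in records],
            "A2": [r.other_allele for r in records],
            "BETA": [r.beta for r in records],
            "SE": [r.se for r in records],
            "P": [r.pval for r in records],
            "EAF": [r.eaf for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gwas(path) -> List[GwasSummaryRecord]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"GWAS summary file missing columns {missing}")
    return [
        GwasSummaryRecord(
            snp_id=str(r.SNP),
            effect_allele=str(r.A1),
            other_allele=str(r.A2),
            beta=float(r.BETA),
            se=float(r.SE),
            pval=float(r.P),
            eaf=float(r.EAF),
        )
        for r in df.itertuples()
    ]


def write_cohort(cohort: pd.DataFrame, path, sep: str = ",") -> None:
    cohort.to_csv(path, sep=sep, index=False)


def read_cohort(path, sep: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)


def write_dosages(panel: GenotypePanel, path, sep: str = "\t") -> None:
    """participants x SNPs dosage matrix; two header-adjacent rows carry the
    allele coding (coded allele counted in the dosage, then the other)."""
    df = panel.to_frame()
    with open(path, "w") as fh:
        fh.write("#coded\t" + "\t".join(panel.coded_allele) + "\n")
        fh.write("#other\t" + "\t".join(panel.other_allele) + "\n")
        df.to_csv(fh, sep=sep, index=False)


def read_dosages(path, sep: str = "\t") -> GenotypePanel:
    with open(path) as fh:
        coded_line = fh.readline().rstrip("\n").split("\t")
        other_line = fh.readline().rstrip("\n").split("\t")
        df = pd.read_csv(fh, sep=sep)
    if coded_line[0] != "#coded" or other_line[0] != "#other":
        raise DataError("dosage file missing #coded/#other allele header lines")
    snp_ids = [c for c in df.columns if c != "participant_id"]
    return GenotypePanel(
        participant_id=df["participant_id"].to_numpy(),
        snp_ids=snp_ids,
        coded_allele=coded_line[1:],
        other_allele=other_line[1:],
        dosages=df[snp_ids].to_numpy(dtype=float),
    )


def write_scores(score_frame: pd.DataFrame, path, sep: str = ",") -> None:
    score_frame.to_csv(path, sep=sep, index=False)


def write_results(rows: Sequence[dict], path, sep: str = ",") -> pd.DataFrame:
    df = pd.DataFrame(list(rows))
    df.to_csv(path, sep=sep, index=False)
    return df
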