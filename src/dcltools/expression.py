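"""Relative expression from qPCR Cq tables by the comparative 2^-ddCq method.

Per replicate, dCq = Cq(target) - Cq(reference gene) within the same sample
and replicate; ddCq subtracts the mean calibrator-sample dCq; the fold
change is 2^-ddCq, averaged over replicates, with the standard deviation of
the per-replicate folds as the error (matching error bars drawn on a linear
fold axis). Amplification efficiency is fixed at 2.0.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("sample", "gene", "replicate", "cq")


def read_cq_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    return validate_cq_table(df)


def validate_cq_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Cq table missing columns: {missing}")
    if not ((df["cq"] > 0) & (df["cq"] < 50)).all():
        raise ValueError("Cq values must lie in (0, 50) cycles")
    return df


def ddcq(
    table: pd.DataFrame,
    ref_gene: str,
    calibrator_sample: str,
    sd_mode: str = "fold",
) -> pd.DataFrame:
    """Relative expression per (gene, sample) by 2^-ddCq.

    Returns a frame with columns gene, sample, fold, sd. ``sd_mode='fold'``
    takes the SD of per-replicate fold values; ``sd_mode='ddcq'`` propagates
    the SD of ddCq onto the fold scale as an asymmetric-range half-width.
    """
    df = validate_cq_table(table)
    if calibrator_sample not in set(df["sample"]):
        raise ValueError(f"calibrator sample {calibrator_sample!r} not in table")
    ref = df[df["gene"] == ref_gene].set_index(["sample", "replicate"])["cq"]
    for sample in df["sample"].unique():
        if sample not in ref.index.get_level_values(0):
            raise ValueError(
                f"reference gene {ref_gene!r} missing in sample {sample!r}"
            )
    targets = df[df["gene"] != ref_gene].copy()

    def ref_cq(row):
        try:
            return ref.loc[(row["sample"], row["replicate"])]
        except KeyError:
            raise ValueError(
                f"reference gene {ref_gene!r} missing for sample "
                f"{row['sample']!r} replicate {row['replicate']!r}"
            ) from None

    targets["dcq"] = targets["cq"] - targets.apply(ref_cq, axis=1)
    rows = []
    for gene, sub in targets.groupby("gene", sort=True):
        cal = sub[sub["sample"] == calibrator_sample]["dcq"]
        if cal.empty:
            raise ValueError(
                f"gene {gene!r} has no calibrator ({calibrator_sample!r}) wells"
            )
        cal_mean = cal.mean()
        for sample, ss in sub.groupby("sample", sort=True):
            ddcq_rep = ss["dcq"] - cal_mean
            folds = np.power(2.0, -ddcq_rep)
            if sd_mode == "fold":
                sd = float(folds.std(ddof=1)) if len(folds) > 1 else 0.0
            elif sd_mode == "ddcq":
                s = float(ddcq_rep.std(ddof=1)) if len(ddcq_rep) > 1 else 0.0
                mean_dd = float(ddcq_rep.mean())
                sd = float(
                    (2.0 ** -(mean_dd - s) - 2.0 ** -(mean_dd + s)) / 2.0
                )
            else:
                raise ValueError(f"unknown sd_mode {sd_mode!r}")
            rows.append(
                {
                    "gene": gene,
                    "sample": sample,
                    "fold": float(folds.mean()),
                    "sd": sd,
                    "calibrator": calibrator_sample,
                }
            )
    out = pd.DataFrame(rows)
    if (out["fold"] <= 0).any():
        raise AssertionError("fold changes must be positive")
    return out


def fold_table_tsv(rel: pd.DataFrame) -> str:
    return "#" + rel.to_csv(sep="\t", index=False)
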