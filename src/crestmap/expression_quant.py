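"""Relative expression from qPCR Ct tables (comparative-Ct method).

Technical replicates are averaged per (sample, tissue, stage, gene); the
target gene is normalized against a reference gene (dCt = Ct_target -
Ct_reference) and scaled to a calibrator sample, reporting fold change
2^-(dCt_sample - dCt_calibrator) with amplification efficiency fixed at 2.
miRNA assays normalized against a small-RNA reference are the same
computation with a different reference gene.
"""

from __future__ import annotations

import warnings

import pandas as pd

CT_COLUMNS = ("sample", "tissue", "stage", "gene", "ct", "rep")


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns {sorted(missing)}")
    return df


def relative_expression(table: pd.DataFrame, target_gene: str,
                        reference_gene: str,
                        calibrator: tuple[str, str]) -> pd.DataFrame:
    """Per-sample fold change of ``target_gene`` relative to the calibrator.

    ``calibrator`` is a (sample, tissue) pair; its fold change is 1 by
    construction.  Samples lacking the reference gene are omitted with a
    warning.
    """
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    means = (
        table.groupby(["sample", "tissue", "stage", "gene"], as_index=False)
        ["ct"].mean()
    )
    wide = means.pivot_table(
        index=["sample", "tissue", "stage"], columns="gene", values="ct"
    )
    for gene in (target_gene, reference_gene):
        if gene not in wide.columns:
            raise ValueError(f"gene {gene!r} absent from Ct table")
    no_ref = wide[reference_gene].isna()
    if no_ref.any():
        dropped = [idx[0] for idx in wide.index[no_ref]]
        warnings.warn(
            f"samples without reference gene omitted: {sorted(set(dropped))}"
        )
        wide = wide[~no_ref]
    wide = wide[~wide[target_gene].isna()]
    dct = wide[target_gene] - wide[reference_gene]
    cal_sample, cal_tissue = calibrator
    cal_rows = [
        idx for idx in dct.index if idx[0] == cal_sample and idx[1] == cal_tissue
    ]
    if not cal_rows:
        raise ValueError(
            f"calibrator ({cal_sample}, {cal_tissue}) absent for both genes"
        )
    cal_dct = float(dct.loc[cal_rows].iloc[0])
    fold = 2.0 ** -(dct - cal_dct)
    out = fold.reset_index()
    out.columns = ["sample", "tissue", "stage", "fold_change"]
    return out
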