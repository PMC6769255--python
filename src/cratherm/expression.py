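"""qRT-PCR relative quantification and site-effect z-scores.

Fold changes use plain delta-delta-Ct with exact doubling per cycle
(efficiency 2, no correction) against a reference gene (CTCF in the
original assays) and an untreated control condition.  Per-site z-scores put
single-site activation and interference effects on a common scale for the
sufficiency-vs-necessity comparison; interference z-scores are negated so
that a higher score always means a more important site.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "CtTable",
    "ddct_fold_change",
    "aggregate_conditions",
    "site_zscores",
]

CT_COLUMNS = ["condition", "gene", "replicate", "ct"]


class CtTable:
    """Raw cycle-threshold values: one row per (condition, gene, replicate)."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in CT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"CtTable missing columns: {missing}")
        ct = frame["ct"]
        if not np.all(np.isfinite(ct)) or (ct <= 0).any():
            raise ValueError("Ct values must be finite and positive")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path) -> "CtTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def ddct_fold_change(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Fold change 2^-ddCt for one sample/control pair of Ct measurements."""
    for v in (ct_target_sample, ct_ref_sample, ct_target_control, ct_ref_control):
        if not np.isfinite(v):
            raise ValueError("Ct inputs must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_control - ct_ref_control)
    return float(2.0 ** -ddct)


def aggregate_conditions(
    table: CtTable,
    reference_gene: str = "CTCF",
    control_condition: str = "control",
) -> pd.DataFrame:
    """Replicate-wise ddCt fold changes aggregated per condition and gene.

    Within each replicate, dCt = Ct(target) - Ct(reference).  Each
    replicate's fold change is taken against the control condition's mean
    dCt, then condition means are rescaled by the control condition's mean
    fold so the control reports exactly 1 (with noisy replicates the raw
    arithmetic mean of control folds sits slightly above 1).  SEM uses the
    n-1 standard deviation; a single replicate reports SEM as NaN.

    Returns a frame with columns gene, condition, mean_rel_expression, sem,
    n_replicates.
    """
    df = table.frame
    if control_condition not in set(df["condition"]):
        raise ValueError(f"control condition {control_condition!r} not in table")

    ref = df[df["gene"] == reference_gene].set_index(["condition", "replicate"])["ct"]
    targets = df[df["gene"] != reference_gene]
    if targets.empty:
        raise ValueError("no target-gene rows in table")

    out = []
    for gene, sub in targets.groupby("gene", sort=True):
        dct = {}
        for row in sub.itertuples():
            key = (row.condition, row.replicate)
            if key not in ref.index:
                raise ValueError(
                    f"reference gene {reference_gene!r} missing for condition "
                    f"{row.condition!r} replicate {row.replicate}"
                )
            dct.setdefault(row.condition, []).append(row.ct - ref.loc[key])
        if control_condition not in dct:
            raise ValueError(f"gene {gene!r} has no control-condition measurements")
        control_dct = float(np.mean(dct[control_condition]))

        folds = {
            cond: 2.0 ** -(np.asarray(vals) - control_dct) for cond, vals in dct.items()
        }
        control_mean = float(np.mean(folds[control_condition]))
        for cond in sorted(folds):
            f = folds[cond] / control_mean
            n = f.size
            sem = float(np.std(f, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            out.append(
                {
                    "gene": gene,
                    "condition": cond,
                    "mean_rel_expression": float(f.mean()),
                    "sem": sem,
                    "n_replicates": int(n),
                }
            )
    return pd.DataFrame(out)


def site_zscores(values, direction: str = "activation") -> np.ndarray:
    """Z-score of each site's single-site effect against the other sites.

    ``values`` holds one relative-expression value per site for one gene;
    the z-score uses the n-1 standard deviation.  For ``direction
    = "interference"`` the scores are negated, so greater knock-down
    (greater necessity) maps to a higher score, mirroring the activation
    axis where stronger induction (greater sufficiency) scores higher.
    """
    if direction not in ("activation", "interference"):
        raise ValueError(f"direction must be 'activation' or 'interference', got {direction!r}")
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 sites for a z-score")
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("zero spread across sites; z-scores undefined")
    z = (x - x.mean()) / sd
    return -z if direction == "interference" else z
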