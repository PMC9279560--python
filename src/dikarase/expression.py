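"""Expression quantification arithmetic: TPM, DEG filtering, qPCR, correlation.

TPM_g = (count_g / length_g) / sum_h(count_h / length_h) * 1e6 per sample.
The DEG rule keeps genes with |log2 fold change| >= 2 and p <= 1e-6
(boundaries inclusive).  qPCR amplification efficiency comes from an
ordinary least-squares standard curve, E = 10^(-1/slope) - 1, and
relative expression from the 2^-ddCt method.  Transcription-factor
association uses Pearson correlation with the t-distributed two-sided
p-value, BH-adjusted across the factor list.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.stats import false_discovery_control


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from a genes x samples count matrix.

    ``lengths`` holds each gene's effective length in bp.  Every non-zero
    sample column sums to 1e6; an all-zero sample stays all-zero with a
    warning.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise ValueError(f"no length for gene {missing!r}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    zero = denom == 0
    if zero.any():
        warnings.warn(
            f"samples with zero counts left all-zero: {list(denom.index[zero])}"
        )
        denom = denom.replace(0, np.nan)
    tpm = rate.div(denom, axis=1) * 1e6
    return tpm.fillna(0.0)


def deg_filter(
    table: pd.DataFrame,
    min_abs_log2fc: float = 2.0,
    max_p: float = 1e-6,
) -> pd.DataFrame:
    """Apply the differential-expression classification rule.

    ``table`` needs columns ``gene``, ``log2fc`` and ``p``.  A gene
    passes when |log2fc| >= ``min_abs_log2fc`` and p <= ``max_p``, both
    inclusive; ``direction`` is up/down by the sign of the fold change.
    """
    vals = table[["log2fc", "p"]].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("log2fc and p must be finite")
    out = table.copy()
    out["pass"] = (out["log2fc"].abs() >= min_abs_log2fc) & (out["p"] <= max_p)
    out["direction"] = np.where(out["log2fc"] > 0, "up",
                                np.where(out["log2fc"] < 0, "down", "none"))
    return out


def log2fc_from_tpm(
    tpm: pd.DataFrame, samples_a, samples_b, pseudocount: float = 1.0
) -> pd.Series:
    """Mean-TPM log2 fold change (A over B) with a pseudocount.

    A plain descriptive estimate; it is not a shrunken model-based fold
    change and is meant for filtering demonstrations only.
    """
    a = tpm[list(samples_a)].mean(axis=1) + pseudocount
    b = tpm[list(samples_b)].mean(axis=1) + pseudocount
    return np.log2(a / b)


# --------------------------------------------------------------------- #
# qPCR


@dataclass(frozen=True)
class StandardCurve:
    slope: float
    intercept: float
    r_squared: float
    efficiency: float


def standard_curve_efficiency(rel_conc, ct) -> StandardCurve:
    """OLS standard curve of Ct on log10(relative concentration).

    Amplification efficiency follows E = 10^(-1/slope) - 1, so a slope
    of -3.3219 (one cycle per twofold dilution) gives E = 1.0.
    """
    x = np.log10(np.asarray(rel_conc, dtype=float))
    y = np.asarray(ct, dtype=float)
    if x.size < 3:
        raise ValueError("standard curve needs at least 3 dilution points")
    if np.allclose(x, x[0]):
        raise ValueError("dilution series has zero variance")
    res = stats.linregress(x, y)
    eff = 10.0 ** (-1.0 / res.slope) - 1.0
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        efficiency=float(eff),
    )


def ddct_fold(
    target_ct: pd.Series, reference_ct: pd.Series, calibrator_sample: str
) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    Both inputs are indexed by sample.  dCt = Ct_target - Ct_reference;
    ddCt subtracts the calibrator sample's dCt; fold = 2^-ddCt (exactly 1
    for the calibrator).

    Raises
    ------
    ValueError
        If the calibrator is absent or a sample lacks a reference Ct.
    """
    if calibrator_sample not in target_ct.index:
        raise ValueError(f"calibrator sample {calibrator_sample!r} missing")
    reference_ct = reference_ct.reindex(target_ct.index)
    if reference_ct.isna().any():
        bad = reference_ct.index[reference_ct.isna()][0]
        raise ValueError(f"no reference-gene Ct for sample {bad!r}")
    dct = target_ct - reference_ct
    ddct = dct - dct.loc[calibrator_sample]
    return pd.DataFrame(
        {"dct": dct, "ddct": ddct, "fold": np.power(2.0, -ddct)}
    )


def analyze_qpcr_plate(plate: pd.DataFrame, calibrator_sample: str):
    """Standard curve plus ddCt folds from a simulated/tidy qPCR plate.

    Expects the layout written by the plate simulator (columns ``role,
    sample, gene, dilution, replicate, ct``).  Returns
    ``(StandardCurve, fold_table)``.
    """
    std = plate[(plate["role"] == "standard") & (plate["gene"] == "target")]
    curve = standard_curve_efficiency(std["dilution"], std["ct"])
    samples = plate[plate["role"] == "sample"]
    mean_ct = samples.groupby(["sample", "gene"])["ct"].mean().unstack()
    folds = ddct_fold(mean_ct["target"], mean_ct["reference"], calibrator_sample)
    return curve, folds


# --------------------------------------------------------------------- #
# Correlation


def correlate_with_tfs(
    expr: pd.DataFrame, target: str, tf_ids, alpha: float = 0.05
) -> pd.DataFrame:
    """Pearson correlation of one target gene against candidate TFs.

    ``expr`` is genes x samples.  Each TF gets Pearson r, the two-sided
    t-test p-value on n-2 degrees of freedom, a BH-adjusted q across the
    tested list, and a sign.  Zero-variance profiles are flagged
    ``undefined`` and excluded from the BH adjustment.
    """
    if expr.shape[1] < 3:
        raise ValueError("correlation needs at least 3 samples")
    y = expr.loc[target].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ValueError(f"target {target!r} has zero variance")
    rows = []
    for tf in tf_ids:
        x = expr.loc[tf].to_numpy(dtype=float)
        if np.std(x) == 0:
            rows.append((tf, np.nan, np.nan, True))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((tf, float(r), float(p), False))
    df = pd.DataFrame(rows, columns=["tf", "r", "p", "undefined"])
    df["q"] = np.nan
    ok = ~df["undefined"]
    if ok.any():
        df.loc[ok, "q"] = false_discovery_control(df.loc[ok, "p"].to_numpy())
    df["sign"] = np.where(df["r"] > 0, "+", np.where(df["r"] < 0, "-", "0"))
    df["significant"] = df["q"] < alpha
    return df


def cluster_tpm(tpm: pd.DataFrame):
    """Average-linkage Euclidean clustering of genes (plotting plumbing)."""
    return linkage(tpm.to_numpy(), method="average", metric="euclidean")
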