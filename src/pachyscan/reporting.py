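"""Feature-table assembly helpers and the correlation / group-comparison
report: Spearman correlation of each feature with piRNA abundance, with
Benjamini-Hochberg adjustment, plus two-sided Wilcoxon comparisons."""

from __future__ import annotations

from importlib.metadata import version, PackageNotFoundError

import numpy as np
import pandas as pd
import scipy.stats
import yaml
from statsmodels.stats.multitest import multipletests

__all__ = ["correlate_with_abundance", "compare_groups", "emit_report"]

P_FLOOR = 2.2e-16
SIGNIFICANCE_ALPHA = 0.05


def correlate_with_abundance(
    table: pd.DataFrame,
    features: list[str],
    abundance_col: str = "abundance_rpm",
    alpha: float = SIGNIFICANCE_ALPHA,
) -> pd.DataFrame:
    """Spearman rho of each feature against piRNA abundance.

    Average ranks for ties, two-sided p values, BH adjustment across the
    feature set; significant iff adjusted p < alpha. Rows with a missing
    value in either column are dropped pairwise. Raw p values below 2.2e-16
    are reported at that floor with ``p_floored`` set.
    """
    y = table[abundance_col].astype(float)
    rows = []
    for feat in features:
        x = table[feat].astype(float)
        ok = x.notna() & y.notna()
        n = int(ok.sum())
        if n < 3 or x[ok].nunique() <= 1 or y[ok].nunique() <= 1:
            rows.append({"feature": feat, "rho": np.nan, "p": np.nan, "n": n})
            continue
        rho, p = scipy.stats.spearmanr(x[ok], y[ok])
        rows.append({"feature": feat, "rho": float(rho), "p": float(p), "n": n})
    out = pd.DataFrame(rows).set_index("feature")
    out["p_floored"] = out["p"] < P_FLOOR
    out["p"] = out["p"].clip(lower=P_FLOOR)
    valid = out["p"].notna()
    out["p_adj"] = np.nan
    if valid.any():
        out.loc[valid, "p_adj"] = multipletests(
            out.loc[valid, "p"], method="fdr_bh"
        )[1]
    out["significant"] = out["p_adj"] < alpha
    return out


def compare_groups(
    values: np.ndarray | pd.Series,
    group_labels: np.ndarray | pd.Series,
    paired: bool = False,
) -> tuple[float, float, bool]:
    """Two-sided Wilcoxon comparison of two groups.

    Rank-sum (Mann-Whitney U) for independent groups; signed-rank for paired
    ones (labels then encode the two conditions in matching order). Returns
    (statistic, p, degenerate); degenerate marks the all-zero-difference
    paired case, where the test is undefined.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {list(uniq)}")
    a = values[labels == uniq[0]]
    b = values[labels == uniq[1]]
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison needs equal group sizes")
        if np.allclose(a, b):
            return float("nan"), float("nan"), True
        stat, p = scipy.stats.wilcoxon(a, b, alternative="two-sided")
    else:
        stat, p = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(stat), float(p), False


def emit_report(
    table: pd.DataFrame,
    correlations: pd.DataFrame,
    config: dict,
    outdir,
) -> dict[str, str]:
    """Write the feature table, correlation table, and a run log (package
    versions, seed, thresholds). Deterministic given its inputs."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": str(outdir / "features.tsv"),
        "correlations": str(outdir / "correlations.tsv"),
        "run_log": str(outdir / "run_log.yaml"),
    }
    table.to_csv(paths["features"], sep="\t")
    correlations.to_csv(paths["correlations"], sep="\t", float_format="%.3g")
    versions = {}
    for pkg in ("pachyscan", "numpy", "scipy", "pandas", "statsmodels"):
        try:
            versions[pkg] = version(pkg)
        except PackageNotFoundError:
            versions[pkg] = "unknown"
    with open(paths["run_log"], "w") as fh:
        yaml.safe_dump({"config": config, "versions": versions}, fh, sort_keys=True)
    return paths
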