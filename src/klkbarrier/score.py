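"""Bootstrap-PCA inflammation score ("PAR2 score") for expression data.

A per-sample indicator of PAR2-downstream signalling built from a fixed
13-probe panel of inflammatory genes.  At every bootstrap repetition a
random background set of probes is drawn, PCA is run on the centred
submatrix of background-plus-panel probes, the principal axis best
separating AD (lesional plus non-lesional) from HC samples is selected
and oriented so AD scores higher, and the sample scores are the panel
submatrix projected onto the panel-restricted axis weights.  The final
score is the mean over repetitions; the spread of the per-probe weights
across repetitions summarises each probe's contribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.decomposition import PCA

from .synth import ProbePanel, default_panel

__all__ = [
    "ExpressionMatrix",
    "ScoreResult",
    "load_expression",
    "center_columns",
    "discriminant_pc",
    "bootstrap_par2_score",
    "scale_to_model",
    "score_gene_association",
]

GROUPS = ("HC", "LAD", "NLAD")


class ExpressionLoadError(ValueError):
    """Malformed expression table or label file."""


@dataclass
class ExpressionMatrix:
    """Samples x probes matrix with group labels."""

    values: pd.DataFrame      # numeric, samples x probes
    groups: pd.Series         # sample -> group label
    centered: bool = False

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()][:3].tolist()
            raise ExpressionLoadError(f"missing values in probe column(s) {bad}")
        missing = self.values.index.difference(self.groups.index)
        if len(missing):
            raise ExpressionLoadError(
                f"sample(s) without group label: {missing.tolist()[:5]}"
            )
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][:3].tolist()
            raise ExpressionLoadError(f"duplicate probe ID(s): {dup}")
        bad_groups = set(self.groups.loc[self.values.index]) - set(GROUPS)
        if bad_groups:
            raise ExpressionLoadError(
                f"unknown group label(s) {sorted(bad_groups)}; expected {GROUPS}"
            )
        self.groups = self.groups.loc[self.values.index]

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def probes(self) -> pd.Index:
        return self.values.columns

    def is_ad(self) -> np.ndarray:
        """AD mask: lesional plus non-lesional samples."""
        return self.groups.isin(["LAD", "NLAD"]).to_numpy()


def load_expression(
    table: str | Path,
    labels: str | Path,
    probes_in_rows: bool = False,
) -> ExpressionMatrix:
    """Read an expression TSV/CSV plus a (sample, group) label CSV.

    ``probes_in_rows`` flips the orientation for tables stored probes x
    samples.  Validation failures name the offending sample or probe.
    """
    table = Path(table)
    sep = "\t" if table.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(table, sep=sep, index_col=0)
    if probes_in_rows:
        df = df.T
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise ExpressionLoadError(f"non-numeric expression column(s): {non_numeric[:3]}")
    lab = pd.read_csv(labels)
    if lab.shape[1] < 2:
        raise ExpressionLoadError("label file needs (sample, group) columns")
    lab = lab.set_index(lab.columns[0])[lab.columns[1]]
    return ExpressionMatrix(values=df.astype(float), groups=lab)


def center_columns(X: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each probe's mean across samples (idempotent)."""
    centered = X.values - X.values.mean(axis=0)
    return ExpressionMatrix(values=centered, groups=X.groups, centered=True)


def _separation_stat(scores: np.ndarray, is_ad: np.ndarray) -> float:
    """Welch-style standardised AD-vs-HC mean difference."""
    a, h = scores[is_ad], scores[~is_ad]
    se = np.sqrt(a.var(ddof=1) / len(a) + h.var(ddof=1) / len(h))
    if se == 0:
        return 0.0
    return float((a.mean() - h.mean()) / se)


def discriminant_pc(
    score_matrix: np.ndarray,
    is_ad: np.ndarray,
    max_components: int | None = None,
) -> tuple[int, float]:
    """Pick the PC axis separating AD from HC, with orientation sign.

    Among the leading columns of the PCA score matrix, returns the index
    of the axis with the largest absolute standardised AD-HC difference
    and the sign that orients it so the AD mean exceeds the HC mean.
    Zero-variance columns are skipped.
    """
    S = np.asarray(score_matrix, dtype=float)
    is_ad = np.asarray(is_ad, dtype=bool)
    if is_ad.sum() < 2 or (~is_ad).sum() < 2:
        raise ValueError("need >= 2 samples on each side of the AD/HC split")
    n_cols = S.shape[1] if max_components is None else min(max_components, S.shape[1])
    best, best_stat = None, 0.0
    for j in range(n_cols):
        col = S[:, j]
        if col.std(ddof=1) <= 1e-12:
            continue
        stat = _separation_stat(col, is_ad)
        if best is None or abs(stat) > abs(best_stat):
            best, best_stat = j, stat
    if best is None:
        raise ValueError("all candidate components are degenerate")
    return best, (1.0 if best_stat >= 0 else -1.0)


@dataclass
class ScoreResult:
    """Bootstrap-averaged per-sample scores and per-probe weight spread."""

    scores: pd.Series                # sample -> mean score over repetitions
    weight_summary: pd.DataFrame     # probe, gene, median, q25, q75
    weights: np.ndarray              # (B, n_panel) raw per-repetition weights
    groups: pd.Series
    B: int
    n_background: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"group": self.groups, "score": self.scores}
        ).rename_axis("sample")


def bootstrap_par2_score(
    X: ExpressionMatrix,
    panel: ProbePanel | None = None,
    n_background: int = 200,
    B: int = 200,
    seed: int = 0,
    variance_cutoff: float = 0.95,
    max_components: int = 10,
) -> ScoreResult:
    """Bootstrap-stabilised PCA score over the inflammatory-gene panel.

    Per repetition: sample ``n_background`` non-panel probes uniformly
    without replacement, run PCA on the centred submatrix of sampled
    plus panel probes, select the AD/HC discriminant axis among the
    leading components explaining ``variance_cutoff`` cumulative
    variance (capped at ``max_components``), and project the panel
    columns onto the axis's panel-restricted weights.  The returned
    score is the mean over the ``B`` repetitions.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    panel = panel or default_panel()
    if len(panel) == 0:
        raise ValueError("empty probe panel")
    missing = [p for p in panel.probes if p not in X.probes]
    if missing:
        raise ExpressionLoadError(f"panel probe(s) absent from matrix: {missing[:5]}")
    Xc = X if X.centered else center_columns(X)
    pool = [p for p in Xc.probes if p not in set(panel.probes)]
    if n_background > len(pool):
        raise ValueError(
            f"n_background={n_background} exceeds the {len(pool)} non-panel probes"
        )
    rng = np.random.default_rng(seed)
    is_ad = Xc.is_ad()
    panel_vals = Xc.values[list(panel.probes)].to_numpy()
    n_panel = len(panel)
    scores_acc = np.zeros((B, len(Xc.samples)))
    weights_acc = np.zeros((B, n_panel))
    for b in range(B):
        chosen = rng.choice(len(pool), size=n_background, replace=False)
        sub = np.hstack(
            [Xc.values[[pool[i] for i in chosen]].to_numpy(), panel_vals]
        )
        n_comp = min(sub.shape[0] - 1, sub.shape[1])
        pca = PCA(n_components=n_comp)
        pc_scores = pca.fit_transform(sub)
        ratios = pca.explained_variance_ratio_
        n_lead = int(np.searchsorted(np.cumsum(ratios), variance_cutoff) + 1)
        n_lead = min(max(n_lead, 1), max_components, n_comp)
        axis, sign = discriminant_pc(pc_scores, is_ad, max_components=n_lead)
        w = sign * pca.components_[axis, -n_panel:]
        weights_acc[b] = w
        scores_acc[b] = panel_vals @ w
    summary = pd.DataFrame(
        {
            "probe": list(panel.probes),
            "gene": list(panel.genes),
            "median": np.median(weights_acc, axis=0),
            "q25": np.percentile(weights_acc, 25, axis=0),
            "q75": np.percentile(weights_acc, 75, axis=0),
        }
    )
    return ScoreResult(
        scores=pd.Series(scores_acc.mean(axis=0), index=Xc.samples, name="score"),
        weight_summary=summary,
        weights=weights_acc,
        groups=Xc.groups,
        B=B,
        n_background=n_background,
        seed=seed,
    )


def scale_to_model(
    scores: pd.Series,
    groups: pd.Series,
    reference_group: str = "HC",
    scale: float = 1.0,
) -> pd.Series:
    """Shift scores so the reference group's median sits at zero.

    Centring on the healthy-control median aligns the data scores with
    the model's zero-inflammation baseline; an optional multiplicative
    ``scale`` maps them onto the model's [PAR2*] axis for overlay plots.
    """
    ref = scores[groups == reference_group]
    if len(ref) == 0:
        raise ValueError(f"reference group {reference_group!r} is empty")
    return (scores - ref.median()) * scale


def score_gene_association(
    scores: Sequence[float], expression: Sequence[float]
) -> dict:
    """Rank correlation between the score and one gene's expression.

    Returns the Spearman coefficient, its p-value and a sign verdict
    ("positive" / "negative" / "none").  Constant input is flagged as
    undefined rather than silently returned as NaN.
    """
    s = np.asarray(scores, dtype=float)
    e = np.asarray(expression, dtype=float)
    if s.shape != e.shape:
        raise ValueError("scores and expression must align")
    if np.ptp(s) == 0 or np.ptp(e) == 0:
        warnings.warn("constant input: correlation undefined", RuntimeWarning,
                      stacklevel=2)
        return {"rho": np.nan, "p_value": np.nan, "sign": "undefined"}
    rho, p = spearmanr(s, e)
    sign = "positive" if rho > 0 else ("negative" if rho < 0 else "none")
    return {"rho": float(rho), "p_value": float(p), "sign": sign}
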