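"""Synthetic microarray cohorts with AD-study structure.

The generator emulates the statistical skeleton of an HC / lesional-AD /
non-lesional-AD expression study on an hgu133a-like platform: a
one-dimensional latent "inflammation level" per sample, a fixed
13-probe panel of seven PAR2-downstream inflammatory genes whose
expression loads linearly on the latent, marker genes (*SPINK5*
negative, *KLK7* positive, *KLK5* non-monotone — mildly rising then
suppressed above a latent threshold), and thousands of pure-noise
background probes.  The latent truth is returned alongside the matrix
so downstream score estimators can be validated for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ProbePanel",
    "SyntheticCohortSpec",
    "SyntheticCohort",
    "default_panel",
    "generate_cohort",
]


@dataclass(frozen=True)
class ProbePanel:
    """Ordered probe IDs with gene labels for the PAR2-downstream panel."""

    probes: tuple[str, ...]
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.probes) != len(self.genes):
            raise ValueError("probes and genes must align")
        if len(set(self.probes)) != len(self.probes):
            raise ValueError("duplicate probe IDs in panel")

    def __len__(self) -> int:
        return len(self.probes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"probe": self.probes, "gene": self.genes})


# The 13 hgu133a probes of the seven PAR2 downstream genes used for the
# inflammation score, in panel order.
_PANEL = (
    ("202637_s_at", "ICAM1"),
    ("202638_s_at", "ICAM1"),
    ("215845_s_at", "ICAM1"),
    ("202859_x_at", "IL8"),
    ("211506_s_at", "IL8"),
    ("207113_s_at", "TNF"),
    ("210228_at", "CSF2"),
    ("210229_s_at", "CSF2"),
    ("208200_at", "IL1A"),
    ("210118_s_at", "IL1A"),
    ("205067_at", "IL1B"),
    ("39402_at", "IL1B"),
    ("207900_at", "CCL17"),
)


def default_panel() -> ProbePanel:
    """The 13-probe / 7-gene PAR2-downstream panel."""
    probes, genes = zip(*_PANEL)
    return ProbePanel(probes=probes, genes=genes)


# Per-probe latent loadings.  CCL17 carries the largest single-probe
# loading, the two IL8 probes jointly rival it — mirroring the
# contribution structure seen in the real weight distributions.
_PANEL_LOADINGS = (0.8, 0.7, 0.6, 1.0, 1.0, 0.7, 0.8, 0.7, 0.9, 0.8, 0.9, 0.8, 1.4)

#: Synthetic marker probes (clearly labelled as such: these IDs are not
#: real platform probes).
MARKER_PROBES = {
    "SPINK5": "SPINK5_syn_at",
    "KLK5": "KLK5_syn_at",
    "KLK7": "KLK7_syn_at",
}


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study-design parameters of a synthetic cohort.

    The defaults are the generator's study conditions: 10 HC, 10
    lesional-AD and 8 non-lesional-AD samples (desk-scale, slightly
    larger than the real cohort), 2000 background probes, latent
    inflammation N(loc, scale) per group with HC lowest and NLAD
    straddling both, homoscedastic probe noise of SD 0.5.
    """

    n_hc: int = 10
    n_lad: int = 10
    n_nlad: int = 8
    latent_hc: tuple[float, float] = (0.0, 0.3)
    latent_lad: tuple[float, float] = (3.0, 0.8)
    latent_nlad: tuple[float, float] = (1.0, 1.0)
    n_background: int = 2000
    noise_sd: float = 0.5
    spink5_loading: float = -0.8
    klk7_loading: float = 0.8
    # KLK5: baseline + mild positive slope, suppressed above a latent
    # threshold so high-inflammation samples show low expression without
    # a globally negative correlation.
    klk5_slope: float = 0.3
    klk5_suppression: float = 1.2
    klk5_threshold: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_hc, self.n_lad) < 2:
            raise ValueError("HC and LAD groups need >= 2 samples each")
        if self.n_nlad < 0 or self.n_background < 1:
            raise ValueError("degenerate cohort spec")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticCohort:
    """Generated expression matrix with ground-truth latent levels."""

    expression: pd.DataFrame  # samples x probes
    groups: pd.Series         # sample -> {"HC", "LAD", "NLAD"}
    latent: pd.Series         # sample -> true inflammation level
    panel: ProbePanel
    spec: SyntheticCohortSpec

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the TSV/CSV files the scoring stage reads."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": outdir / "expression.tsv",
            "labels": outdir / "labels.csv",
            "latent": outdir / "latent_truth.csv",
            "panel": outdir / "panel.csv",
        }
        self.expression.rename_axis("sample").to_csv(paths["expression"], sep="\t")
        self.groups.rename("group").rename_axis("sample").to_csv(paths["labels"])
        self.latent.rename("latent").rename_axis("sample").to_csv(paths["latent"])
        self.panel.to_frame().to_csv(paths["panel"], index=False)
        return paths


def generate_cohort(spec: SyntheticCohortSpec | None = None) -> SyntheticCohort:
    """Draw one cohort from the latent-factor model.

    Expression of panel and marker probes is loading * latent plus
    independent Gaussian noise; background probes are pure noise around
    probe-specific baselines.  Fully determined by ``spec.seed``.
    """
    spec = spec or SyntheticCohortSpec()
    rng = np.random.default_rng(spec.seed)
    panel = default_panel()

    groups, latents, names = [], [], []
    for label, n, (loc, scale) in (
        ("HC", spec.n_hc, spec.latent_hc),
        ("LAD", spec.n_lad, spec.latent_lad),
        ("NLAD", spec.n_nlad, spec.latent_nlad),
    ):
        for i in range(n):
            names.append(f"{label}_{i + 1:02d}")
            groups.append(label)
            latents.append(rng.normal(loc, scale))
    z = np.array(latents)
    n_samples = len(z)

    cols: dict[str, np.ndarray] = {}
    noise = lambda: rng.normal(0.0, spec.noise_sd, size=n_samples)
    for probe, loading in zip(panel.probes, _PANEL_LOADINGS):
        cols[probe] = loading * z + noise()
    cols[MARKER_PROBES["SPINK5"]] = spec.spink5_loading * z + noise()
    cols[MARKER_PROBES["KLK7"]] = spec.klk7_loading * z + noise()
    cols[MARKER_PROBES["KLK5"]] = (
        spec.klk5_slope * z
        - spec.klk5_suppression * np.clip(z - spec.klk5_threshold, 0.0, None)
        + noise()
    )
    baselines = rng.normal(0.0, 1.0, size=spec.n_background)
    bg = baselines + rng.normal(0.0, 1.0, size=(n_samples, spec.n_background))
    for j in range(spec.n_background):
        cols[f"bg_{j + 1:05d}_at"] = bg[:, j]

    X = pd.DataFrame(cols, index=pd.Index(names, name="sample"))
    return SyntheticCohort(
        expression=X,
        groups=pd.Series(groups, index=X.index, name="group"),
        latent=pd.Series(z, index=X.index, name="latent"),
        panel=panel,
        spec=spec,
    )
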