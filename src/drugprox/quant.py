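"""Isobaric-tag (8-plex) protein ratio quantification with a Cauchy noise model.

An 8-plex isobaric labelling experiment reports, for every identified
peptide, eight reporter-ion intensities (channels 113-119 and 121), each
channel corresponding to one treatment condition.  Relative protein
abundance in a treatment channel is expressed as the ratio of its reporter
intensity to the reference channel (untreated cells in normoxia, channel
113), aggregated over the protein's peptides on the log10 scale.

Significance of a protein ratio is assessed against a Cauchy null: the
pooled protein log10-ratios are assumed to follow a Cauchy(location, scale)
distribution under "no regulation", the heavy tails absorbing both
technical and biological ratio variability.  A protein is called
up-regulated when its ratio exceeds 1 with two-sided p <= alpha, and
down-regulated when the ratio is below 1 with p <= alpha.

The functions here operate on plain pandas DataFrames:

``PeptideQuantTable``
    columns ``peptide``, ``protein``, ``i113`` ... ``i121`` (positive
    reporter intensities, arbitrary units).
``ProteinRatioTable``
    columns ``protein``, ``channel``, ``log10_ratio``, ``ratio``,
    ``n_peptides`` and, once :func:`call_regulation` has run, ``p_value``
    and ``call``.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

#: Reporter-ion channel labels of the 8-plex reagent (121, not 120, is the
#: eighth label -- a quirk of the reagent chemistry).
CHANNELS: tuple[int, ...] = (113, 114, 115, 116, 117, 118, 119, 121)

#: Reference channel: untreated cells under normoxia.
REFERENCE_CHANNEL: int = 113

#: Column name of a channel's intensity in a peptide quant table.
def intensity_col(channel: int) -> str:
    return f"i{channel}"


@dataclasses.dataclass(frozen=True)
class ChannelDesign:
    """Map from reporter channel to experimental condition.

    The default is the KDAC-inhibition / hypoxia design: TSA inhibits
    class I/II/IV lysine deacetylases, nicotinamide (NAM) the sirtuins;
    channels 117-121 are the hypoxic arm.
    """

    conditions: dict[int, str] = dataclasses.field(
        default_factory=lambda: {
            113: "control_normoxia",
            114: "TSA_normoxia",
            115: "NAM_normoxia",
            116: "TSA_NAM_normoxia",
            117: "control_hypoxia",
            118: "TSA_hypoxia",
            119: "NAM_hypoxia",
            121: "TSA_NAM_hypoxia",
        }
    )
    reference_channel: int = REFERENCE_CHANNEL

    def __post_init__(self) -> None:
        if self.reference_channel not in self.conditions:
            raise ValueError("reference channel missing from the design")
        labels = list(self.conditions.values())
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be unique")

    @property
    def treatment_channels(self) -> tuple[int, ...]:
        return tuple(c for c in self.conditions if c != self.reference_channel)


DEFAULT_DESIGN = ChannelDesign()


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """Cauchy null model for protein log10-ratios.

    ``location`` and ``scale`` are in log10-ratio units; for a Cauchy the
    quartiles sit at location +/- scale, which is what the quartile fit
    exploits.
    """

    location: float
    scale: float
    n_fit: int

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("Cauchy scale must be positive")


class DegenerateFitError(ValueError):
    """Raised when the noise fit would be degenerate (zero spread)."""


def normalize_channels(table: pd.DataFrame, method: str = "median") -> pd.DataFrame:
    """Remove per-channel multiplicative bias (loading / labelling bias).

    ``method="median"`` rescales every channel so that all channel medians
    equal the reference channel's median; ``method="none"`` is the
    identity.  Returns a new DataFrame.
    """
    if table.empty:
        raise ValueError("cannot normalize an empty quant table")
    if method == "none":
        return table.copy()
    if method != "median":
        raise ValueError(f"unknown normalization method: {method!r}")
    out = table.copy()
    ref_median = float(out[intensity_col(REFERENCE_CHANNEL)].median())
    for c in CHANNELS:
        col = intensity_col(c)
        med = float(out[col].median())
        if med <= 0:
            raise ValueError(f"channel {c} has non-positive median intensity")
        out[col] = out[col] * (ref_median / med)
    return out


_AGGREGATES = ("mean", "intensity_weighted_mean", "median")


def protein_log_ratios(
    table: pd.DataFrame,
    design: ChannelDesign = DEFAULT_DESIGN,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Aggregate peptide-level ratios to per-protein log10-ratios.

    For every treatment channel ``c`` the peptide log-ratio is
    ``log10(i_c / i_ref)``.  Aggregation over a protein's peptides:

    ``mean``
        unweighted mean of peptide log-ratios.  This is the default
        because the mean of iid Cauchy variables is again Cauchy with the
        *same* scale (stability), so the Cauchy null model stays exactly
        calibrated at the protein level.
    ``intensity_weighted_mean``
        ``sum(w_i x_i) / sum(w_i)`` with ``w_i = i_c + i_ref``.
    ``median``
        per-protein median of peptide log-ratios.

    Rows with a non-positive or missing intensity in either channel of a
    pair are dropped for that channel only (no imputation).
    """
    if aggregate not in _AGGREGATES:
        raise ValueError(f"unknown aggregate {aggregate!r}; choose from {_AGGREGATES}")
    if table.empty:
        raise ValueError("empty quant table")
    ref_col = intensity_col(design.reference_channel)
    frames = []
    for c in design.treatment_channels:
        col = intensity_col(c)
        ic = table[col].to_numpy(dtype=float)
        ir = table[ref_col].to_numpy(dtype=float)
        usable = np.isfinite(ic) & np.isfinite(ir) & (ic > 0) & (ir > 0)
        if not usable.any():
            continue
        sub = pd.DataFrame(
            {
                "protein": table["protein"].to_numpy()[usable],
                "x": np.log10(ic[usable] / ir[usable]),
                "w": ic[usable] + ir[usable],
            }
        )
        if aggregate == "mean":
            agg = sub.groupby("protein", sort=True)["x"].agg(["mean", "size"])
            agg = agg.rename(columns={"mean": "log10_ratio", "size": "n_peptides"})
        elif aggregate == "median":
            agg = sub.groupby("protein", sort=True)["x"].agg(["median", "size"])
            agg = agg.rename(columns={"median": "log10_ratio", "size": "n_peptides"})
        else:
            sub["wx"] = sub["w"] * sub["x"]
            g = sub.groupby("protein", sort=True)
            agg = pd.DataFrame(
                {
                    "log10_ratio": g["wx"].sum() / g["w"].sum(),
                    "n_peptides": g["x"].size(),
                }
            )
        agg = agg.reset_index()
        agg["channel"] = c
        frames.append(agg)
    if not frames:
        raise ValueError("no usable peptide rows in any channel")
    out = pd.concat(frames, ignore_index=True)
    out["ratio"] = 10.0 ** out["log10_ratio"]
    out["n_peptides"] = out["n_peptides"].astype(int)
    return out[["protein", "channel", "log10_ratio", "ratio", "n_peptides"]]


def fit_cauchy_noise(
    ratio_table: pd.DataFrame,
    channels_for_fit: Iterable[int] | None = None,
    method: str = "quartile",
) -> NoiseModel:
    """Fit the Cauchy null to pooled protein log10-ratios.

    ``method="quartile"`` (default): location = median, scale = half the
    interquartile range -- for a Cauchy the quartiles sit at
    location +/- scale, so this is consistent, closed-form and robust.
    ``method="mle"`` uses the maximum-likelihood fit instead.

    Requires at least 10 observations; raises :class:`DegenerateFitError`
    if the data have no spread.
    """
    x = ratio_table["log10_ratio"]
    if channels_for_fit is not None:
        chan = set(channels_for_fit)
        x = x[ratio_table["channel"].isin(chan)]
    x = x.to_numpy(dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError(
            f"need at least 10 protein log-ratios to fit the noise model, got {x.size}"
        )
    if method == "quartile":
        location = float(np.median(x))
        q1, q3 = np.percentile(x, [25.0, 75.0])
        scale = float((q3 - q1) / 2.0)
    elif method == "mle":
        location, scale = stats.cauchy.fit(x)
        location, scale = float(location), float(scale)
    else:
        raise ValueError(f"unknown fit method: {method!r}")
    if scale <= 0:
        raise DegenerateFitError("all observations identical: Cauchy scale would be 0")
    return NoiseModel(location=location, scale=scale, n_fit=int(x.size))


def ratio_pvalue(log10_ratio, model: NoiseModel):
    """Two-sided p-value of a log10-ratio under the Cauchy null.

    p = 2 (1 - F(|x - location| / scale)) with F the standard Cauchy CDF
    F(z) = 1/2 + arctan(z)/pi, i.e. p = 1 - 2 arctan(|z|)/pi.  Accepts a
    scalar or an array.
    """
    z = np.abs(np.asarray(log10_ratio, dtype=float) - model.location) / model.scale
    p = 1.0 - 2.0 * np.arctan(z) / np.pi
    if p.ndim == 0:
        return float(p)
    return p


def call_regulation(
    ratio_table: pd.DataFrame, model: NoiseModel, alpha: float = 0.05
) -> pd.DataFrame:
    """Attach p-values and up/down/ns calls to a protein ratio table.

    up   <=> ratio > 1 and p <= alpha
    down <=> ratio < 1 and p <= alpha
    ns   otherwise (a ratio of exactly 1 is always ns).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    out = ratio_table.copy()
    out["p_value"] = ratio_pvalue(out["log10_ratio"].to_numpy(), model)
    sig = out["p_value"] <= alpha
    out["call"] = "ns"
    out.loc[sig & (out["ratio"] > 1.0), "call"] = "up"
    out.loc[sig & (out["ratio"] < 1.0), "call"] = "down"
    return out


def write_ratio_table(ratio_table: pd.DataFrame, path) -> None:
    ratio_table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ratio_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
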