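"""Diagnostic plots: L-function curves, the cohort metric scatter, and
the survival-ordered MIM smooth with its centroid band."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_l_function", "plot_metric_scatter", "plot_mim_association"]


def _get_ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_l_function(estimate, envelope=None, ax=None):
    """L(r) against the CSR diagonal, optionally with a simulation
    envelope (r_grid, lo, hi) from :func:`cilgibbs.spatial.csr_envelope`."""
    ax = _get_ax(ax)
    r = estimate.r_grid
    ax.plot(r, r, "k--", lw=1, label="CSR: L(r) = r")
    if envelope is not None:
        er, lo, hi = envelope
        ax.fill_between(er, lo, hi, color="0.85", label="CSR envelope")
    ax.plot(r, estimate.L_hat, "C0-", label=r"$\hat{L}(r)$")
    ax.set_xlabel(r"r ($\mu$m)")
    ax.set_ylabel(r"L(r) ($\mu$m)")
    ax.legend()
    return ax


def plot_metric_scatter(records, ax=None, group_col="group"):
    """z-scored inhibition metric M(r) per patient, coloured by group."""
    ax = _get_ax(ax)
    colors = {"Gibbs": "C0", "Invasion": "C3"}
    for name, sub in records.groupby(group_col):
        ax.scatter(sub["z_G_r"], sub["z_L_r"], s=14,
                   c=colors.get(name, "C2"), label=str(name), alpha=0.7)
    ax.set_xlabel(r"$z_{G_r}$")
    ax.set_ylabel(r"$z_{L_r}$")
    ax.legend()
    return ax


def plot_mim_association(assoc, ax=None):
    """Survival-ordered vs randomized MIM smooths with the centroid band
    and, if present, the establishment point (from
    :func:`cilgibbs.survival.associate_group`)."""
    ax = _get_ax(ax)
    inc, rnd, band = assoc["increasing"], assoc["randomized"], assoc["band"]
    idx = np.arange(len(inc.smoothed))
    half = band.multiplier * band.sd
    ax.axhspan(band.center - half, band.center + half, color="0.9",
               label=f"centroid $\\pm$ {band.multiplier:g} SD")
    ax.plot(idx, inc.smoothed, "C0-", label="increasing survival")
    ax.plot(idx, rnd.smoothed, color="0.4", ls="--", label="randomized")
    if assoc["established"]:
        ax.axvline(assoc["establishment_index"], color="C3", lw=1,
                   label=f"establishment (index "
                         f"{assoc['establishment_index']}, "
                         f"{assoc['establishment_days']:.0f} d)")
    ax.set_xlabel("patient index (ordered)")
    ax.set_ylabel("smoothed MIM")
    ax.legend(fontsize=8)
    return ax
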