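"""Report figures: polar displacement plots and VDF galleries."""

from __future__ import annotations

import numpy as np

from .burgers import model_f
from .preprocess import sqrt_display


def plot_polar(profile, fit, path):
    """Polar plot of measured |displacement| vs azimuth with the fitted
    azimuthal model overlaid (lobes repeat with 180 deg period)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(4.2, 4.2))
    ax = fig.add_subplot(projection="polar")
    phi = profile.phi
    d = np.abs(profile.displacement)
    err = profile.uncertainty
    ax.errorbar(np.radians(phi), d, yerr=err, fmt="o", ms=4, color="tab:blue",
                label="measured")
    ax.errorbar(np.radians(phi + 180.0), d, yerr=err, fmt="o", ms=4,
                color="tab:blue", alpha=0.4)
    if fit is not None and fit.ok:
        th = np.linspace(0, 360, 721)
        ax.plot(np.radians(th),
                model_f(th, fit.amp_A, fit.shape_B, fit.phase_C),
                color="tab:red", lw=1.5, label="fit")
    ax.set_title("bend-contour displacement (nm) vs azimuth")
    ax.legend(loc="lower left", fontsize=8)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_vdf_gallery(vdfs, path, ncol=4):
    """Square-root-scaled gallery of VDF images labelled by azimuth."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(vdfs)
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(2.2 * ncol, 2.2 * nrow),
                             squeeze=False)
    for ax in axes.ravel():
        ax.axis("off")
    for ax, v in zip(axes.ravel(), vdfs):
        ax.imshow(sqrt_display(v.image), cmap="gray")
        ax.set_title(f"phi={v.g.phi:.0f} deg"
                     + ("" if v.g.usable else " (unusable)"), fontsize=8)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
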