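"""Plotting helpers: wavelet amplitude surfaces, coupling-function
surfaces per protocol stage, and directionality time courses."""

from __future__ import annotations

import numpy as np

from .io import StageProtocol
from .measures import CouplingGrid
from .model import PhaseCouplingResults
from .wavelet import WaveletSpectrum

__all__ = ["plot_wavelet_amplitude", "plot_coupling_grid",
           "plot_stage_grids", "plot_directionality"]


def _axes(nrows=1, ncols=1, **kw):
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt.subplots(nrows, ncols, **kw)


def plot_wavelet_amplitude(spectrum: WaveletSpectrum, ax=None):
    """Time–frequency amplitude surface on a log frequency axis."""
    if ax is None:
        fig, ax = _axes(figsize=(8, 4))
    else:
        fig = ax.figure
    mesh = ax.pcolormesh(spectrum.times, spectrum.frequencies,
                         spectrum.amplitude(), shading="auto")
    ax.set_yscale("log")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    fig.colorbar(mesh, ax=ax, label="|X|")
    return fig


def plot_coupling_grid(grid: CouplingGrid, ax=None):
    """Surface plot of a coupling function over the 2π×2π phase grid."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    if ax is None:
        fig = plt.figure(figsize=(4, 3.5))
        ax = fig.add_subplot(projection="3d")
    else:
        fig = ax.figure
    M = grid.size
    phi1, phi2 = np.meshgrid(np.arange(M) * 2 * np.pi / M,
                             np.arange(M) * 2 * np.pi / M, indexing="ij")
    ax.plot_surface(phi2, phi1, grid.values, cmap="viridis",
                    rstride=max(M // 32, 1), cstride=max(M // 32, 1))
    ax.set_xlabel(r"$\phi_{Resp}$")
    ax.set_ylabel(r"$\phi_{Card}$")
    ax.set_title(grid.label)
    return fig


def plot_stage_grids(results: PhaseCouplingResults, protocol: StageProtocol,
                     M: int = 64):
    """One coupling-function surface per protocol stage."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    grids = results.stage_grids(protocol, M=M)
    fig = plt.figure(figsize=(3.2 * max(len(grids), 1), 3.2))
    for i, (stage, grid) in enumerate(grids.items(), start=1):
        ax = fig.add_subplot(1, len(grids), i, projection="3d")
        grid.label = f"stage {stage}"
        plot_coupling_grid(grid, ax=ax)
    fig.tight_layout()
    return fig


def plot_directionality(results: PhaseCouplingResults,
                        protocol: StageProtocol | None = None, ax=None):
    """D(t) time course with optional stage boundaries."""
    if ax is None:
        fig, ax = _axes(figsize=(8, 3))
    else:
        fig = ax.figure
    ax.plot(results.midtimes, results.directionality(), "o-", ms=3)
    ax.axhline(0.0, color="k", lw=0.5)
    if protocol is not None:
        for label, start, end in protocol.stages:
            ax.axvline(start, color="grey", lw=0.5, ls="--")
            ax.text(0.5 * (start + end), 1.02, label, ha="center",
                    transform=ax.get_xaxis_transform())
    ax.set_xlabel("time (s)")
    ax.set_ylabel("D(t)")
    ax.set_ylim(-1.05, 1.05)
    return fig
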