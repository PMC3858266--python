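"""Convenience plots for library contrasts (tables are the primary output)."""

from __future__ import annotations

import numpy as np

from srnaome.preprocess import LibraryProfile


def plot_length_distribution(profiles: dict[str, LibraryProfile], basis: str = "redundant"):
    """Grouped bar chart of per-length shares across libraries."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    lengths = sorted({l for p in profiles.values() for l in p.per_length.index})
    x = np.arange(len(lengths))
    width = 0.8 / max(1, len(profiles))
    for i, (lib, prof) in enumerate(profiles.items()):
        shares = [float(prof.share(basis).get(l, 0.0)) for l in lengths]
        ax.bar(x + i * width, shares, width, label=lib)
    ax.set_xticks(x + width * (len(profiles) - 1) / 2)
    ax.set_xticklabels([str(l) for l in lengths])
    ax.set_xlabel("sRNA length (nt)")
    ax.set_ylabel(f"share of {basis} reads")
    ax.legend()
    fig.tight_layout()
    return fig


def plot_category_composition(compositions: dict, basis: str = "redundant_fraction"):
    """Grouped bar chart of annotation-category shares across libraries."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    cats = list(next(iter(compositions.values())).index)
    x = np.arange(len(cats))
    width = 0.8 / max(1, len(compositions))
    for i, (lib, comp) in enumerate(compositions.items()):
        ax.bar(x + i * width, comp[basis].to_numpy(), width, label=lib)
    ax.set_xticks(x + width * (len(compositions) - 1) / 2)
    ax.set_xticklabels(cats, rotation=45, ha="right")
    ax.set_ylabel(basis.replace("_", " "))
    ax.legend()
    fig.tight_layout()
    return fig
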