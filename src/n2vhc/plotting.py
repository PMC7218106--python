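"""Basic dendrogram rendering helpers (matplotlib)."""

from __future__ import annotations

from scipy.cluster.hierarchy import dendrogram as _scipy_dendrogram

from .treecut import Dendrogram


def plot_dendrogram(dend: Dendrogram, ax=None, **kwargs):
    """Render a merge tree with leaf labels; returns the axes.

    Extra keyword arguments pass through to
    :func:`scipy.cluster.hierarchy.dendrogram`.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, dend.n_leaves * 0.25), 4))
    _scipy_dendrogram(dend.Z, labels=dend.ids, ax=ax,
                      leaf_rotation=90, **kwargs)
    ax.set_ylabel("merge height")
    return ax
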