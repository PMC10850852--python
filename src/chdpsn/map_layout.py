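"""2D embedding of the patient distance matrix — the "map" view.

t-SNE consumes the precomputed fused distance matrix directly (no
re-featurisation).  To make layouts reproducible and independent of the
order in which patients appear in the cohort file, the initial coordinates
of each point are derived deterministically from a hash of the patient id
and the seed; the optimisation itself is then run with a fixed random
state.  Exact coordinates remain floating-point sensitive, so order
invariance is structural (cluster geometry), not bitwise.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .similarity import DistanceMatrix

__all__ = ["MapLayout", "tsne_embed", "export_layout"]


@dataclass
class MapLayout:
    """Per-patient 2D coordinates plus the embedding parameters and a
    fingerprint of the source matrix."""

    ids: list[str]
    coords: np.ndarray  # n x 2
    perplexity: float
    n_iter: int
    seed: int
    matrix_fingerprint: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"patient_id": self.ids, "x": self.coords[:, 0],
             "y": self.coords[:, 1]}
        )


def _id_seeded_init(ids: list[str], seed: int) -> np.ndarray:
    """Initial 2D positions derived from md5(seed:patient_id) — identical
    for a patient regardless of cohort ordering."""
    coords = np.empty((len(ids), 2))
    for i, pid in enumerate(ids):
        h = hashlib.md5(f"{seed}:{pid}".encode()).digest()
        sub = np.random.default_rng(int.from_bytes(h[:8], "little"))
        coords[i] = sub.normal(scale=1e-4, size=2)
    return coords


def _fingerprint(values: np.ndarray) -> str:
    return hashlib.md5(np.ascontiguousarray(values).tobytes()).hexdigest()


def tsne_embed(
    dm: DistanceMatrix,
    perplexity: float = 30.0,
    n_iter: int = 1000,
    seed: int = 0,
) -> MapLayout:
    """Embed a distance matrix into 2D with t-SNE on precomputed
    distances.

    The requested perplexity is capped at (n - 1) / 3 (t-SNE requires
    perplexity < number of samples, and small maps need a smaller
    neighbourhood size).
    """
    n = len(dm.ids)
    if n < 4:
        raise ValueError(f"need at least 4 patients to embed, got {n}")
    if perplexity <= 0:
        raise ValueError("perplexity must be positive")
    perplexity = min(perplexity, (n - 1) / 3)
    tsne = TSNE(
        n_components=2,
        metric="precomputed",
        perplexity=perplexity,
        max_iter=n_iter,
        init=_id_seeded_init(dm.ids, seed),
        random_state=seed,
    )
    coords = tsne.fit_transform(np.asarray(dm.values, dtype=float))
    return MapLayout(
        ids=list(dm.ids),
        coords=np.asarray(coords, dtype=float),
        perplexity=perplexity,
        n_iter=n_iter,
        seed=seed,
        matrix_fingerprint=_fingerprint(dm.values),
    )


def export_layout(
    layout: MapLayout,
    annotations: dict[str, object],
    out_prefix: str,
    annotation_name: str = "annotation",
) -> tuple[str, str]:
    """Write the layout as a colored scatter (PNG) and a TSV of
    id, x, y, annotation.  ``annotations`` must cover every patient."""
    missing = [pid for pid in layout.ids if pid not in annotations]
    if missing:
        raise KeyError(
            f"annotation missing for {len(missing)} patient(s), "
            f"e.g. {missing[:3]}"
        )
    df = layout.to_frame()
    df[annotation_name] = [annotations[pid] for pid in layout.ids]
    tsv_path = f"{out_prefix}.tsv"
    df.to_csv(tsv_path, sep="\t", index=False)

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    values = sorted(set(df[annotation_name].astype(str)))
    cmap = plt.get_cmap("tab10")
    for i, v in enumerate(values):
        sel = df[annotation_name].astype(str) == v
        ax.scatter(df.loc[sel, "x"], df.loc[sel, "y"], s=12,
                   color=cmap(i % 10), label=str(v), alpha=0.8)
    ax.legend(title=annotation_name, fontsize=8)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    png_path = f"{out_prefix}.png"
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    return png_path, tsv_path
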