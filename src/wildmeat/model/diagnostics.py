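"""Posterior draw container, convergence diagnostics and persistence."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


def split_rhat(draws: np.ndarray) -> np.ndarray:
    """Split potential scale reduction factor per parameter.

    ``draws`` has shape (chains, iterations, parameters).  Each chain is
    split in half (so a single chain still yields a valid diagnostic) and
    the classic between/within variance ratio is computed via arviz.
    """
    import arviz as az

    c, n, d = draws.shape
    half = n // 2
    split = np.concatenate(
        [draws[:, :half, :], draws[:, half : 2 * half, :]], axis=0
    )
    ds = az.convert_to_dataset(split)
    return np.asarray(az.rhat(ds, method="rank")["x"])


@dataclass
class PosteriorDraws:
    """Posterior draws with named scalar columns.

    ``draws`` has shape (chains, post-warmup iterations, parameters);
    ``names`` labels each scalar column; ``slices`` maps block names to
    column ranges; ``stats`` carries sampler diagnostics (step sizes,
    divergence counts, clamped-record counts).
    """

    draws: np.ndarray
    names: list
    slices: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def get(self, name: str) -> np.ndarray:
        """Draws for one block (by block name) or one scalar (by column name)."""
        if name in self.slices:
            return self.flat()[:, self.slices[name]]
        try:
            col = self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown parameter {name!r}") from None
        return self.flat()[:, col]

    def rhat(self) -> pd.Series:
        return pd.Series(split_rhat(self.draws), index=self.names, name="rhat")

    def summary(self) -> pd.DataFrame:
        """Posterior mean/median/sd, central 95% interval, and split-Rhat."""
        flat = self.flat()
        q = np.percentile(flat, [2.5, 50.0, 97.5], axis=0)
        return pd.DataFrame(
            {
                "mean": flat.mean(axis=0),
                "median": q[1],
                "sd": flat.std(axis=0, ddof=1),
                "q2.5": q[0],
                "q97.5": q[2],
                "rhat": split_rhat(self.draws),
            },
            index=self.names,
        )

    def convergence_report(self, threshold: float = 1.01) -> dict:
        rhat = self.rhat()
        worst = rhat.idxmax()
        return {
            "max_rhat": float(rhat.max()),
            "worst_parameter": str(worst),
            "n_above_threshold": int((rhat > threshold).sum()),
            "threshold": threshold,
            "divergences": int(self.stats.get("divergences", 0)),
            "clamped_frequencies": int(self.stats.get("clamped_frequencies", 0)),
        }

    def save(self, path) -> None:
        """Columnar draws (npz) plus a JSON index of names and stats."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), draws=self.draws)
        index = {
            "names": list(self.names),
            "slices": {k: [v.start, v.stop] for k, v in self.slices.items()},
            "stats": self.stats,
        }
        path.with_suffix(".json").write_text(json.dumps(index, indent=1))

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        path = Path(path)
        draws = np.load(path.with_suffix(".npz"))["draws"]
        index = json.loads(path.with_suffix(".json").read_text())
        return cls(
            draws=draws,
            names=index["names"],
            slices={k: slice(a, b) for k, (a, b) in index["slices"].items()},
            stats=index["stats"],
        )
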