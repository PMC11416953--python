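"""Per-timestep episode records, exportable as tidy CSV."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

COLUMNS = ["t", "x", "y", "kappa", "action", "r_plus", "r_minus", "td_error"]


@dataclass
class EpisodeLog:
    """Append-only record of an episode: pose, action, rewards, TD error.

    ``meta`` carries episode-level results (success flag, path length, route
    order ...); arbitrary extra per-step columns may be appended via
    ``extras``.
    """

    rows: list[dict] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def append(
        self,
        t: float,
        x: float,
        y: float,
        kappa: float,
        action: int | None = None,
        r_plus: float = 0.0,
        r_minus: float = 0.0,
        td_error: float | None = None,
        **extras,
    ) -> None:
        self.rows.append(
            dict(
                t=t, x=x, y=y, kappa=kappa,
                action=-1 if action is None else int(action),
                r_plus=r_plus, r_minus=r_minus,
                td_error=float("nan") if td_error is None else td_error,
                **extras,
            )
        )

    def __len__(self) -> int:
        return len(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        if not self.rows:
            return pd.DataFrame(columns=COLUMNS)
        return pd.DataFrame(self.rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @property
    def path_length(self) -> float:
        df = self.to_dataframe()
        if len(df) < 2:
            return 0.0
        dx = df["x"].diff().dropna()
        dy = df["y"].diff().dropna()
        return float(((dx**2 + dy**2) ** 0.5).sum())
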