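"""Level-removal transformation: subtract each subject's own mean outcome.

Clustering raw trajectories groups subjects mainly by outcome *level*.
Subtracting each subject's mean over their observed visits removes the
subject-specific vertical offset so that the mixture model clusters
trajectory *shapes* instead.

Centering is computed in exact rational arithmetic (``fractions.Fraction``)
with a single correct rounding per output value.  This makes the transform
exactly invariant to subject-specific vertical shifts whenever the shifted
input values are themselves exact sums, and makes each subject's centered
values sum to zero up to one rounding per value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .panel import PanelError, TrajectoryPanel

__all__ = ["CenteredPanel", "center_trajectories"]


@dataclass(frozen=True)
class CenteredPanel:
    """A trajectory panel after per-subject mean removal.

    ``records`` holds the centered values (subject-then-age order);
    ``subject_means`` the stored per-subject means that invert the
    transform; ``dropped_subjects`` lists subjects excluded because a
    single observation carries no shape information once centered.
    """

    records: pd.DataFrame
    subject_means: pd.Series
    dropped_subjects: tuple

    @property
    def subjects(self) -> list:
        return list(self.records["subject_id"].unique())

    @property
    def n_subjects(self) -> int:
        return self.records["subject_id"].nunique()

    def iter_subjects(self):
        for sid, grp in self.records.groupby("subject_id", sort=True):
            yield sid, grp["age"].to_numpy(), grp["value"].to_numpy()

    def restrict(self, subject_ids) -> "CenteredPanel":
        keep = set(subject_ids)
        df = self.records[self.records["subject_id"].isin(keep)].reset_index(drop=True)
        if len(df) == 0:
            raise PanelError("no records after restriction")
        means = self.subject_means[self.subject_means.index.isin(keep)]
        return CenteredPanel(df, means, self.dropped_subjects)

    def uncenter(self) -> TrajectoryPanel:
        """Add stored means back, recovering the input panel."""
        df = self.records.copy()
        means = self.subject_means
        df["value"] = [
            float(Fraction(v) + Fraction(means[s]))
            for s, v in zip(df["subject_id"], df["value"])
        ]
        return TrajectoryPanel(df)

    def shifted(self, offsets: pd.Series) -> "CenteredPanel":
        """Centered panel with per-subject constants added to the stored means.

        Utility for reasoning about shift invariance: centered values are
        untouched because a vertical shift only moves the subject mean.
        """
        means = self.subject_means + offsets.reindex(self.subject_means.index)
        return CenteredPanel(self.records.copy(), means, self.dropped_subjects)


def center_trajectories(panel: TrajectoryPanel) -> CenteredPanel:
    """Subtract each subject's observed-visit mean from their values.

    Subjects with a single record are dropped with a warning: their centered
    vector is identically zero and contributes nothing to a shape model.
    """
    rows = []
    means: dict = {}
    dropped = []
    for sid, ages, values in panel.iter_subjects():
        if len(values) < 2:
            dropped.append(sid)
            continue
        fracs = [Fraction(float(v)) for v in values]
        mean = sum(fracs) / len(fracs)
        means[sid] = float(mean)
        for age, f in zip(ages, fracs):
            rows.append((sid, age, float(f - mean)))
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} subject(s) with a single record: "
            f"{dropped[:5]}",
            stacklevel=2,
        )
    if not rows:
        raise PanelError("no subject has >= 2 records; nothing to center")
    df = pd.DataFrame(rows, columns=["subject_id", "age", "value"])
    return CenteredPanel(df, pd.Series(means, name="subject_mean"), tuple(dropped))
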