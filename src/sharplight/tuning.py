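"""Voxel tuning: preferred-stimulus classification and the congruency ×
preference signature that separates sharpening from cancellation.

Each voxel is classified by the sign of a paired t contrast of its betas
for observed index vs little finger movements across all run × condition
cells (t > 0 → index-preferred, t < 0 → little-preferred, t = 0 →
excluded). Univariate betas are then averaged per congruency ×
preference cell: under sharpening, activity on congruent trials is
suppressed only in voxels tuned *away* from the observed stimulus
(non-preferred cells); under cancellation, only in voxels tuned *toward*
it. The analysis uses unsmoothed native-grid betas throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import ClusterSet
from .design import CONDITIONS
from .effects import AnovaResult, TTestResult, paired_t, rm_anova
from .simulate import BetaSet


@dataclass
class TuningMap:
    """Per-voxel preference t statistic and binary preferred-stimulus label.

    ``preference`` holds +1 for index-preferred, −1 for little-preferred
    and 0 for excluded (t exactly zero, or outside the mask).
    """

    grid: "object"
    t_map: np.ndarray
    preference: np.ndarray
    subject_id: str = "sub-01"

    def preferred_label(self, voxel: tuple[int, int, int]) -> str | None:
        p = self.preference[voxel]
        return {1: "index", -1: "little", 0: None}[int(p)]


def voxel_preference(betas: BetaSet, include_no_move: bool = True) -> TuningMap:
    """Classify each voxel's preferred stimulus from an index-vs-little contrast.

    The paired t runs across all (run, condition) cells — including
    no-move cells by default, configurable to move-only — on the
    difference beta(index) − beta(little).
    """
    conditions = [c for c in CONDITIONS if include_no_move or c != "no_move"]
    cells = [(r, c) for r in betas.runs for c in conditions if (r, c, "index") in betas.data]
    if len(cells) < 2:
        raise ValueError(f"voxel preference needs >= 2 paired cells, found {len(cells)}")
    diffs = np.stack([betas[(r, c, "index")] - betas[(r, c, "little")] for r, c in cells])
    m = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(m))
        t = np.where((sd == 0) & (mean == 0), 0.0, t)
        t = np.where((sd == 0) & (mean != 0), np.sign(mean) * np.inf, t)
    mask = betas.grid.mask
    pref = np.zeros(betas.grid.shape, dtype=np.int8)
    pref[mask & (t > 0)] = 1
    pref[mask & (t < 0)] = -1
    t = np.where(mask, t, np.nan)
    return TuningMap(grid=betas.grid, t_map=t, preference=pref, subject_id=betas.subject_id)


def preference_signal_table(
    betas_by_subject: dict[str, BetaSet],
    tuning_by_subject: dict[str, TuningMap],
    rois: ClusterSet,
) -> pd.DataFrame:
    """Univariate betas per subject × cluster × congruency × preference.

    For an index-preferring voxel, congruent trials showing an index
    finger feed the congruent-preferred cell and those showing a little
    finger the congruent-non-preferred cell (and symmetrically for
    little-preferring voxels). Values average over runs and over the
    cluster's non-excluded voxels. A cluster whose voxels are all
    excluded (t = 0) is an error.
    """
    stim_of = {1: "index", -1: "little"}
    rows = []
    for subject, betas in sorted(betas_by_subject.items()):
        tuning = tuning_by_subject[subject]
        if tuning.preference.shape != betas.grid.shape:
            raise ValueError(f"tuning map and betas for {subject} are not on one grid")
        for cl in rois:
            voxels = [v for v in cl.voxels if tuning.preference[v] != 0]
            if not voxels:
                raise ValueError(f"cluster {cl.label}: all voxels excluded (t = 0) for {subject}")
            for cond in ("congruent", "incongruent"):
                for status in ("preferred", "nonpreferred"):
                    vals = []
                    for v in voxels:
                        pref = stim_of[int(tuning.preference[v])]
                        stim = pref if status == "preferred" else ("little" if pref == "index" else "index")
                        vals.extend(betas[(r, cond, stim)][v] for r in betas.runs)
                    rows.append(
                        {
                            "subject_id": subject,
                            "cluster": cl.label,
                            "congruency": cond,
                            "preference": status,
                            "value": float(np.mean(vals)),
                        }
                    )
    return pd.DataFrame(rows)


@dataclass
class SignatureResult:
    """Verdict on which population-code account the data support."""

    verdict: str  # sharpening | cancellation | mixed | none
    anova: AnovaResult
    t_preferred: TTestResult
    t_nonpreferred: TTestResult
    alpha: float

    def summary(self) -> str:
        lines = [self.anova.summary()]
        lines.append(
            f"  congruent vs incongruent, preferred cells:     t({self.t_preferred.df}) = "
            f"{self.t_preferred.t:.3f}, p = {self.t_preferred.p:.4f}"
        )
        lines.append(
            f"  congruent vs incongruent, non-preferred cells: t({self.t_nonpreferred.df}) = "
            f"{self.t_nonpreferred.t:.3f}, p = {self.t_nonpreferred.p:.4f}"
        )
        lines.append(f"  verdict: {self.verdict}")
        return "\n".join(lines)


def sharpening_signature(cell_table: pd.DataFrame, alpha: float = 0.05) -> SignatureResult:
    """Classify a congruency × preference cell table as sharpening,
    cancellation, mixed or none.

    Runs the (cluster ×) congruency × preference within-subject ANOVA,
    then paired congruent-vs-incongruent tests within each preference
    status collapsed over clusters. Suppression (congruent < incongruent,
    p < alpha) confined to non-preferred cells reads as sharpening; to
    preferred cells, as cancellation; both, mixed; neither, none.
    """
    factors = ["congruency", "preference"]
    if "cluster" in cell_table.columns and cell_table["cluster"].nunique() > 1:
        factors = ["cluster", *factors]
    anova = rm_anova(cell_table, factors)

    def cells(status: str) -> tuple[np.ndarray, np.ndarray]:
        sub = cell_table[cell_table["preference"] == status]
        per = sub.pivot_table(index="subject_id", columns="congruency", values="value")
        return per["congruent"].to_numpy(), per["incongruent"].to_numpy()

    t_pref = paired_t(*cells("preferred"))
    t_nonpref = paired_t(*cells("nonpreferred"))
    supp_pref = t_pref.p < alpha and t_pref.t < 0
    supp_nonpref = t_nonpref.p < alpha and t_nonpref.t < 0
    if supp_nonpref and not supp_pref:
        verdict = "sharpening"
    elif supp_pref and not supp_nonpref:
        verdict = "cancellation"
    elif supp_pref and supp_nonpref:
        verdict = "mixed"
    else:
        verdict = "none"
    return SignatureResult(
        verdict=verdict, anova=anova, t_preferred=t_pref, t_nonpreferred=t_nonpref, alpha=alpha
    )


def univariate_congruency(cell_table: pd.DataFrame) -> TTestResult:
    """Main effect of congruency on the univariate signal (extra contrast)."""
    per = cell_table.pivot_table(index="subject_id", columns="congruency", values="value")
    return paired_t(per["congruent"].to_numpy(), per["incongruent"].to_numpy())
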