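"""Encode longitudinal bud-stage observations into binary transition datasets.

Buds are scored on an ordinal scale 0–6 (0 dormant … 6 needles elongating);
stages 1 and 2 are merged into a single label ``12`` because they are hard
to tell apart in the field.  Each of the five consecutive transitions
(0→12, 12→3, 3→4, 4→5, 5→6) is analyzed as a binomial outcome: within a
transition's risk set, 0 marks a bud that remained in the source stage at
a census and 1 marks its first census at or beyond the target stage.

Because censuses are weekly, a bud can skip stages between two visits; a
skipping census counts as the success record for every transition it
completes.  After its first success a bud leaves that transition's risk
set.  A bud whose very first census is already at or beyond the target was
never observed at risk and contributes nothing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

#: Ordered merged stage labels.
STAGES = (0, 12, 3, 4, 5, 6)

#: The five transitions, in fixed order.
TRANSITIONS = ("0->12", "12->3", "3->4", "4->5", "5->6")

#: transition id -> (source stage, target stage)
TRANSITION_STAGES = {
    "0->12": (0, 12),
    "12->3": (12, 3),
    "3->4": (3, 4),
    "4->5": (4, 5),
    "5->6": (5, 6),
}

_STAGE_RANK = {s: i for i, s in enumerate(STAGES)}

BUD_KEY = ["site", "year", "species", "seed_source", "tree", "bud"]


def stage_rank(stage: int) -> int:
    """Position of a merged stage label in the ordered stage set."""
    try:
        return _STAGE_RANK[int(stage)]
    except KeyError:
        raise ValueError(f"unknown merged stage label {stage!r}; expected one of {STAGES}")


def merge_stages(raw: pd.DataFrame) -> pd.DataFrame:
    """Relabel raw field stages 0–6 to the merged set {0, 12, 3, 4, 5, 6}.

    Stages 1 and 2 both become ``12``; everything else (including an
    already-merged ``12``) is unchanged.  Raises on stages outside 0–6.
    """
    obs = raw.copy()
    stages = obs["stage"].astype(int)
    bad = ~(stages.between(0, 6) | (stages == 12))
    if bad.any():
        raise ValueError(
            f"stages outside 0..6 at rows {list(obs.index[bad])[:10]}: "
            f"{sorted(stages[bad].unique())}"
        )
    obs["stage"] = stages.where(~stages.isin((1, 2)), 12)
    return obs


@dataclass
class ValidationReport:
    """Outcome of trajectory validation.

    ``violations`` lists one dict per offending bud with the reason;
    ``clean_obs`` is the input minus offending buds (only populated in
    lenient mode).
    """

    n_buds: int
    violations: list = field(default_factory=list)
    clean_obs: pd.DataFrame | None = None

    @property
    def clean(self) -> bool:
        return not self.violations


def validate_trajectories(obs: pd.DataFrame, mode: str = "report") -> ValidationReport:
    """Check every bud's trajectory for stage regressions and duplicate censuses.

    mode: ``"report"`` lists violations; ``"strict"`` raises on the first;
    ``"lenient"`` drops offending buds (count logged) and returns the
    cleaned table in the report.
    """
    if mode not in ("report", "strict", "lenient"):
        raise ValueError(f"unknown validation mode {mode!r}")
    violations = []
    bad_keys = []
    for key, grp in obs.groupby(BUD_KEY, sort=False):
        grp = grp.sort_values("doy")
        if grp["doy"].duplicated().any():
            dup = grp.loc[grp["doy"].duplicated(), "doy"].tolist()
            item = {"bud": key, "problem": "duplicate_census", "doy": dup}
        else:
            ranks = grp["stage"].map(stage_rank)
            if (ranks.diff().dropna() < 0).any():
                item = {
                    "bud": key,
                    "problem": "stage_regression",
                    "trajectory": grp["stage"].tolist(),
                }
            else:
                continue
        if mode == "strict":
            raise ValueError(f"trajectory violation: {item}")
        violations.append(item)
        bad_keys.append(key)
    report = ValidationReport(n_buds=obs.groupby(BUD_KEY).ngroups, violations=violations)
    if mode == "lenient":
        if bad_keys:
            idx = obs.set_index(BUD_KEY).index
            keep = ~idx.isin(bad_keys)
            report.clean_obs = obs[keep].copy()
            logger.warning("dropped %d invalid buds of %d", len(bad_keys), report.n_buds)
        else:
            report.clean_obs = obs.copy()
    return report


def encode_transition(
    obs: pd.DataFrame,
    transition_id: str,
    mode: str = "strict",
) -> pd.DataFrame:
    """Binary risk-set records for one transition.

    strict (default): records at exactly the source stage are outcome 0;
    the bud's first record at or beyond the target stage is outcome 1
    (even if intermediate stages were skipped); records before reaching
    the source stage and after the first success are excluded.

    cumulative: every record from the bud's first census through its first
    success, outcome = 1(stage >= target).

    In both modes a bud already at/beyond the target at its first census
    was never observed at risk and contributes nothing.
    """
    if transition_id not in TRANSITION_STAGES:
        raise ValueError(f"unknown transition {transition_id!r}; expected one of {TRANSITIONS}")
    if mode not in ("strict", "cumulative"):
        raise ValueError(f"unknown encoding mode {mode!r}")
    source, target = TRANSITION_STAGES[transition_id]
    target_rank = stage_rank(target)

    obs = obs.sort_values(BUD_KEY + ["doy"], kind="mergesort")
    records = []
    for key, grp in obs.groupby(BUD_KEY, sort=False):
        stages = grp["stage"].to_numpy()
        doys = grp["doy"].to_numpy()
        ranks = [stage_rank(s) for s in stages]
        # first census at/beyond the target stage
        t_m = next((i for i, r in enumerate(ranks) if r >= target_rank), None)
        if t_m == 0:
            continue  # never observed below target: not at risk
        end = t_m if t_m is not None else len(stages)
        for i in range(end):
            if mode == "strict" and stages[i] != source:
                continue
            records.append((*key, int(doys[i]), 0))
        if t_m is not None:
            records.append((*key, int(doys[t_m]), 1))
    out = pd.DataFrame(records, columns=BUD_KEY + ["doy", "outcome"])
    out.insert(0, "transition", transition_id)
    return out


def build_transition_datasets(
    obs: pd.DataFrame,
    covariates: pd.DataFrame,
    mode: str = "strict",
) -> dict[str, pd.DataFrame]:
    """The five transition datasets with covariates joined on (site, year, doy).

    The join is exact — a missing covariate row for any observation DOY is
    an error naming the (site, year, doy).  Per-dataset record counts are
    logged; all-empty output (e.g. every bud already flushed at the first
    census) triggers a warning.
    """
    cov_keys = covariates.set_index(["site", "year", "doy"]).index
    datasets = {}
    total = 0
    for tid in TRANSITIONS:
        enc = encode_transition(obs, tid, mode=mode)
        if len(enc):
            missing = enc.set_index(["site", "year", "doy"]).index.difference(cov_keys)
            if len(missing):
                raise ValueError(
                    f"covariate table missing (site, year, doy) rows: {list(missing[:10])}"
                )
        merged = enc.merge(covariates, on=["site", "year", "doy"], how="left")
        datasets[tid] = merged
        logger.info("transition %s: %d records (%d successes)",
                    tid, len(merged), int(merged["outcome"].sum()) if len(merged) else 0)
        total += len(merged)
    if total == 0:
        warnings.warn("all transition datasets are empty", stacklevel=2)
    return datasets
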