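"""Measurement layer: cell assemblies, ignition latency, sustained activity.

A cell belongs to a pattern's cell assembly (CA) if at any of the 30
poststimulation steps its firing rate reaches at least half of the rate of
the maximally responsive cell of its area at that step, provided that
maximum is at least 0.2.  T_max is the step (1..30) at which an area's
summed rate peaks; the sustained memory period (SMP) is the number of
consecutive steps from T_max during which the summed rate stays at or above
the prestimulation mean + 2 SD.  The statistics helpers reproduce the
repeated-measures design: each network instance contributes one value per
condition (architecture x area), averaged over its 14 patterns.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .protocol import TrialRecording

logger = logging.getLogger(__name__)

CA_MIN_PEAK = 0.2
CA_FRACTION = 0.5


@dataclasses.dataclass
class CAResult:
    member_cells: dict[str, np.ndarray]   # area -> within-area cell indices
    size_per_area: dict[str, int]
    pattern_id: int
    architecture: str
    instance_seed: int
    trials_trained: int | None = None

    @property
    def size_total(self) -> int:
        return int(sum(self.size_per_area.values()))


@dataclasses.dataclass
class DynamicsResult:
    t_max: dict[str, int]        # area -> step index in [1, 30]
    smp: dict[str, int]          # area -> duration in steps (>= 0)
    prestim_mean: dict[str, float]
    prestim_sd: dict[str, float]
    pattern_id: int
    architecture: str
    instance_seed: int


def extract_cell_assembly(cell_traces: np.ndarray, areas: tuple[str, ...],
                          min_peak: float = CA_MIN_PEAK,
                          fraction: float = CA_FRACTION,
                          per_step: bool = True) -> dict[str, np.ndarray]:
    """Identify CA member cells per area from (n_cells, n_steps) poststimulus
    excitatory traces (flat area-major cell layout).

    ``per_step=True`` applies the membership criterion against each step's
    own area maximum (the default reading); ``per_step=False`` uses the
    area's global maximum over all steps instead (sensitivity variant).
    """
    n_areas = len(areas)
    area_cells = cell_traces.shape[0] // n_areas
    members = {}
    for a, name in enumerate(areas):
        block = cell_traces[a * area_cells:(a + 1) * area_cells]
        if per_step:
            m = block.max(axis=0)                      # per-step area max
            valid = m >= min_peak
            hit = block >= fraction * m[None, :]
            member = np.any(hit & valid[None, :], axis=1)
        else:
            m = block.max()
            member = (m >= min_peak) & np.any(block >= fraction * m, axis=1)
        members[name] = np.nonzero(member)[0]
    return members


def compute_tmax(area_sums: np.ndarray) -> np.ndarray:
    """Step index (1-based) of the peak summed rate per area over the 30
    poststimulation steps; ties resolved to the earliest step."""
    return np.argmax(area_sums, axis=1) + 1


def compute_smp(area_sums: np.ndarray, prestim_sums: np.ndarray,
                t_max: np.ndarray, epsilon: float = 1e-9) -> np.ndarray:
    """Consecutive steps from T_max (inclusive) with summed rate >= prestim
    mean + 2 SD; the first sub-threshold step ends the interval.  A zero
    prestimulation SD gets an ``epsilon`` added to the threshold."""
    mean = prestim_sums.mean(axis=1)
    sd = prestim_sums.std(axis=1, ddof=1)
    if np.any(sd == 0):
        logger.info("zero prestimulation SD; adding epsilon=%g", epsilon)
    thr = mean + 2.0 * sd + np.where(sd == 0, epsilon, 0.0)
    out = np.zeros(len(t_max), dtype=int)
    for a in range(len(t_max)):
        run = 0
        for t in range(t_max[a] - 1, area_sums.shape[1]):
            if area_sums[a, t] >= thr[a]:
                run += 1
            else:
                break
        out[a] = run
    return out


def analyze_recording(rec: TrialRecording, areas: tuple[str, ...],
                      trials_trained: int | None = None,
                      min_peak: float = CA_MIN_PEAK,
                      fraction: float = CA_FRACTION,
                      ) -> tuple[CAResult, DynamicsResult]:
    members = extract_cell_assembly(rec.post_cell_traces, areas,
                                    min_peak, fraction)
    ca = CAResult(members, {a: len(v) for a, v in members.items()},
                  rec.pattern_id, rec.architecture, rec.instance_seed,
                  trials_trained)
    tmax = compute_tmax(rec.post_area_sums)
    smp = compute_smp(rec.post_area_sums, rec.prestim_sums, tmax)
    mean = rec.prestim_sums.mean(axis=1)
    sd = rec.prestim_sums.std(axis=1, ddof=1)
    dyn = DynamicsResult({a: int(t) for a, t in zip(areas, tmax)},
                         {a: int(s) for a, s in zip(areas, smp)},
                         {a: float(m) for a, m in zip(areas, mean)},
                         {a: float(s) for a, s in zip(areas, sd)},
                         rec.pattern_id, rec.architecture, rec.instance_seed)
    return ca, dyn


def growth_rates(sizes: pd.Series, per: float = 100.0) -> pd.Series:
    """Centred finite-difference growth rate of mean CA size versus training
    amount, in cells per ``per`` learning trials.

    ``sizes`` is indexed by checkpoint (presentations per pattern).  Interior
    checkpoints use the centred difference over the two neighbours; the
    endpoints use one-sided differences.
    """
    cps = np.asarray(sizes.index, dtype=float)
    vals = sizes.to_numpy(dtype=float)
    if len(cps) < 2:
        raise ValueError("need at least two checkpoints")
    grad = np.gradient(vals, cps)
    return pd.Series(grad * per, index=sizes.index, name="growth_rate")


def within_subject_sem(df: pd.DataFrame, subject: str, value: str,
                       group: list[str]) -> pd.Series:
    """SEM after removing between-subject variance: subtract each subject's
    grand mean, add back the overall mean, then compute the SEM of the
    adjusted values per condition."""
    adj = df[value] - df.groupby(subject)[value].transform("mean") \
        + df[value].mean()
    out = df.assign(_adj=adj).groupby(group)["_adj"]
    return out.sem().rename("sem_within")


def _require_balanced(df: pd.DataFrame, subject: str,
                      factors: list[str]) -> None:
    counts = df.groupby([subject] + factors).size()
    full = df[subject].nunique()
    for f in factors:
        full *= df[f].nunique()
    if len(counts) != full or counts.nunique() != 1:
        expected = pd.MultiIndex.from_product(
            [df[subject].unique()] + [df[f].unique() for f in factors],
            names=[subject] + factors)
        missing = expected.difference(counts.index)
        raise ValueError(f"unbalanced design; missing cells: {list(missing)}")


def rm_anova(df: pd.DataFrame, dv: str, subject: str,
             within: list[str]) -> pd.DataFrame:
    """Repeated-measures ANOVA with Greenhouse-Geisser correction (one or
    two within-subject factors); values must be one per subject x condition."""
    import pingouin as pg
    _require_balanced(df, subject, within)
    w = within[0] if len(within) == 1 else within
    return pg.rm_anova(data=df, dv=dv, within=w, subject=subject,
                       detailed=True, correction=True)


def tukey_contrasts(df: pd.DataFrame, dv: str, group: str) -> pd.DataFrame:
    """Tukey HSD over the levels of ``group`` (pooled across subjects)."""
    import pingouin as pg
    return pg.pairwise_tukey(data=df, dv=dv, between=group)


def summarize_and_test(dynamics: pd.DataFrame,
                       areas: tuple[str, ...]) -> dict:
    """Comparative statistics of the dynamics table.

    ``dynamics`` must be tidy with columns instance, architecture, area,
    t_max, smp -- one row per instance x architecture x area (already
    averaged over patterns).  Returns a JSON-serialisable report with the
    two rm-ANOVAs, adjacent-area T_max contrasts per architecture, and
    per-area architecture contrasts on SMP.
    """
    _require_balanced(dynamics, "instance", ["architecture", "area"])
    report: dict = {"anova": {}, "tmax_adjacent": {}, "smp_by_area": {}}
    n_subj = dynamics["instance"].nunique()
    for dv in ("t_max", "smp"):
        if n_subj >= 2:
            tab = rm_anova(dynamics, dv, "instance", ["architecture", "area"])
            report["anova"][dv] = tab.to_dict(orient="records")
        else:
            report["anova"][dv] = "not computed (fewer than 2 instances)"
    for arch, sub in dynamics.groupby("architecture"):
        means = sub.groupby("area")["t_max"].mean()
        rows = []
        for a, b in zip(areas[:-1], areas[1:]):
            rows.append({"pair": f"{a}-{b}",
                         "mean_diff": float(means[b] - means[a])})
        report["tmax_adjacent"][arch] = rows
    piv = dynamics.pivot_table(index=["instance", "area"],
                               columns="architecture", values="smp")
    for area in areas:
        sub = piv.xs(area, level="area")
        report["smp_by_area"][area] = {
            "mean_HA": float(sub["HA"].mean()),
            "mean_MA": float(sub["MA"].mean()),
            "mean_diff": float((sub["HA"] - sub["MA"]).mean()),
        }
    report["within_subject_sem"] = {
        dv: within_subject_sem(dynamics, "instance", dv,
                               ["architecture", "area"]).to_dict()
        for dv in ("t_max", "smp")
    }
    report["within_subject_sem"] = {
        dv: {f"{arch}/{area}": v for (arch, area), v in d.items()}
        for dv, d in report["within_subject_sem"].items()
    }
    return report
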