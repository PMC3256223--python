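"""In-silico perturbation experiments on a miRNA-signaling network.

Four study designs:

* single-miRNA over-expression with log2(perturbed/control) readouts
  (heatmap rows per miRNA, small changes masked);
* dose scans over a miRNA gene-expression range (direct-target and
  downstream steady states per dose);
* activation-threshold scans: the minimal receptor gene-expression level at
  which all downstream readouts become active under constant ligand input,
  with and without a repressing miRNA;
* an anti-miRNA screen: each inhibitor applied alone against its cognate
  over-expressed miRNA, scored by a paired t-test over the concentration
  changes of all model components and ranked by p-value.

Experiment conventions follow the simulated study conditions: EGF/ATP/ADP
clamped at 1 nM, all species starting at 0, and the expression of every
miRNA other than the one under study set to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import KineticConfig, Marking, steady_state
from .model import (
    ModelNetwork,
    Role,
    TargetTable,
    UnknownEntityError,
    mirna_gene_id,
    mrna_id,
)

__all__ = [
    "PerturbationSpec",
    "ReadoutSet",
    "HeatmapResult",
    "ScreenResult",
    "control_state",
    "overexpression_experiment",
    "dose_scan",
    "activation_threshold",
    "anti_mirna_screen",
    "t_test_p_value",
    "rank_anti_mirnas",
    "target_count_histogram",
    "log2_ratio",
]

#: floor used when forming log2 ratios of concentrations (~well below one
#: molecule per cell; keeps 0/0 comparisons at ratio 0)
RATIO_FLOOR = 1e-12

#: detection floor (nM) applied before log-transforming concentrations for
#: the screen's t-test; bounds the contribution of species that vanish
LOG_FLOOR = 1e-6

#: default activation criterion: steady state above ~one copy per cell (nM)
ACTIVATION_EPSILON = 1e-3

#: default over-expression level for a miRNA gene (nM); upper end of the
#: physiological mRNA abundance range
OVEREXPRESSION_LEVEL = 10.0

#: saturating anti-miRNA dose, as a multiple of the miRNA gene level
SATURATING_DOSE_FACTOR = 100.0

#: simulation settings for the in-silico studies: conventional
#: (non-consuming) catalysis, so a repressed cascade component lowers the
#: activity downstream of it rather than being compensated by reduced
#: consumption of its kinase, and a step budget long enough for the slow
#: ligand-receptor decay arm to equilibrate
EXPERIMENT_CONFIG = KineticConfig(consume_enzymes=False, max_steps=1000)


@dataclass
class PerturbationSpec:
    """One experimental perturbation: which entity, which level(s)."""

    kind: str  # mirna_overexpression | mirna_knockout | anti_mirna_dose | gene_dose
    entity: str
    levels: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        kinds = {"mirna_overexpression", "mirna_knockout", "anti_mirna_dose", "gene_dose"}
        if self.kind not in kinds:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        self.levels = tuple(float(x) for x in self.levels)
        if any(x < 0 for x in self.levels):
            raise ValueError("perturbation levels must be >= 0")
        if self.kind == "mirna_knockout":
            self.levels = (0.0,)


@dataclass
class ReadoutSet:
    """A named list of readout entities (mRNAs or active proteins)."""

    name: str
    ids: tuple[str, ...]

    @classmethod
    def mrnas(cls, model: ModelNetwork) -> "ReadoutSet":
        ids = tuple(e.id for e in model.entities.values()
                    if e.role is Role.MRNA and e.compartment.value == "cytoplasm")
        return cls("mRNAs", ids)

    @classmethod
    def active_proteins(cls, model: ModelNetwork) -> "ReadoutSet":
        """Phosphorylated/active species downstream of the receptor."""
        ids = tuple(eid for eid in model.entities
                    if eid.startswith("P-") or eid.startswith("Active-"))
        return cls("active_proteins", ids)

    def validate(self, model: ModelNetwork) -> None:
        for eid in self.ids:
            if eid not in model.entities:
                raise UnknownEntityError(f"readout {eid!r} not in model")


@dataclass
class HeatmapResult:
    """Matrix of log2 ratios (perturbations x readouts) plus the white mask."""

    ratios: pd.DataFrame
    mask_threshold: float = 0.001

    @property
    def mask(self) -> pd.DataFrame:
        """True where |log2 ratio| < threshold (rendered white, kept in data)."""
        return self.ratios.abs() < self.mask_threshold


@dataclass
class ScreenResult:
    """Anti-miRNA screen output: states, p-values and the ranking inputs."""

    p_values: pd.Series  # index: anti-miRNA id
    end_states: dict[str, Marking] = field(default_factory=dict)
    control_states: dict[str, Marking] = field(default_factory=dict)
    heatmap: Optional[HeatmapResult] = None
    baseline: Optional[Marking] = None  # no-miRNA control
    dose_levels: tuple[float, ...] = ()


# ---------------------------------------------------------------------------
# helpers

def _mirna_gene_clamps(model: ModelNetwork) -> list[str]:
    out = []
    for e in model.entities.values():
        if e.role is Role.GENE and e.id.endswith("_gene"):
            out.append(e.id)
    return out


def _with_clamps(model: ModelNetwork, overrides: dict[str, float]) -> ModelNetwork:
    m = model.copy()
    for eid, v in overrides.items():
        m.clamp(eid, v)
    return m


def _silenced(model: ModelNetwork, keep: Optional[str] = None,
              level: float = 0.0) -> dict[str, float]:
    """Clamp overrides zeroing all miRNA genes except ``keep`` at ``level``."""
    overrides = {g: 0.0 for g in _mirna_gene_clamps(model)}
    if keep is not None:
        overrides[mirna_gene_id(keep)] = level
    return overrides


def log2_ratio(perturbed: Marking, control: Marking,
               ids: Sequence[str]) -> pd.Series:
    """log2(perturbed / control) per readout, floored at RATIO_FLOOR."""
    vals = {}
    for eid in ids:
        p = max(float(perturbed[eid]), RATIO_FLOOR)
        c = max(float(control[eid]), RATIO_FLOOR)
        vals[eid] = math.log2(p / c)
    return pd.Series(vals)


# ---------------------------------------------------------------------------
# experiments

def control_state(model: ModelNetwork, cfg: KineticConfig = EXPERIMENT_CONFIG,
                  no_mirnas: bool = False) -> Marking:
    """Steady-state marking under baseline conditions (no perturbation).

    ``no_mirnas=True`` additionally zeroes every miRNA gene, giving the
    miRNA-free reference used by over-expression and reversal comparisons.
    """
    m = _with_clamps(model, _silenced(model)) if no_mirnas else model
    return steady_state(m, cfg=cfg)


def overexpression_experiment(model: ModelNetwork, mirna: str, level: float,
                              readouts: Optional[ReadoutSet] = None,
                              cfg: KineticConfig = EXPERIMENT_CONFIG,
                              mask_threshold: float = 0.001) -> pd.Series:
    """log2 steady-state ratios of over-expressing one miRNA vs no miRNA.

    All other miRNA genes are silenced in both conditions; repression of a
    direct target shows up as a negative ratio.
    """
    if mirna_gene_id(mirna) not in model.entities:
        raise UnknownEntityError(f"miRNA {mirna!r} not in model")
    readouts = readouts or ReadoutSet.mrnas(model)
    readouts.validate(model)
    ctrl = steady_state(_with_clamps(model, _silenced(model)), cfg=cfg)
    pert = steady_state(_with_clamps(model, _silenced(model, keep=mirna, level=level)),
                        cfg=cfg)
    return log2_ratio(pert, ctrl, readouts.ids)


def dose_scan(model: ModelNetwork, spec: PerturbationSpec,
              readouts: Optional[ReadoutSet] = None,
              cfg: KineticConfig = EXPERIMENT_CONFIG) -> pd.DataFrame:
    """Steady-state readout levels across a range of perturbation doses.

    Rows are doses (nM), columns readout entities.  For a repressing miRNA,
    direct-target columns are monotonically non-increasing in dose.
    """
    if len(spec.levels) < 2 and spec.kind != "mirna_knockout":
        raise ValueError("dose scan needs at least 2 levels")
    readouts = readouts or ReadoutSet.mrnas(model)
    readouts.validate(model)
    rows = {}
    for level in spec.levels:
        if spec.kind in ("mirna_overexpression", "mirna_knockout"):
            overrides = _silenced(model, keep=spec.entity, level=level)
        elif spec.kind == "gene_dose":
            overrides = {spec.entity: level}
        else:  # anti_mirna_dose
            overrides = {f"anti-{spec.entity}": level}
        state = steady_state(_with_clamps(model, overrides), cfg=cfg)
        rows[level] = {eid: state[eid] for eid in readouts.ids}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "dose_nM"
    return df


def activation_threshold(model: ModelNetwork, driver_gene: str,
                         levels: Sequence[float],
                         readouts: ReadoutSet,
                         criterion: Optional[Callable[[float], bool]] = None,
                         cfg: KineticConfig = EXPERIMENT_CONFIG) -> Optional[float]:
    """Smallest driver-gene level at which every readout is active.

    ``levels`` must be strictly increasing.  The default criterion is a
    steady state above ACTIVATION_EPSILON (~one molecule per cell).  Returns
    None (sentinel) when the criterion is never met.
    """
    levels = [float(x) for x in levels]
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValueError("levels must be strictly increasing")
    readouts.validate(model)
    crit = criterion or (lambda x: x > ACTIVATION_EPSILON)
    for level in levels:
        state = steady_state(_with_clamps(model, {driver_gene: level}), cfg=cfg)
        if all(crit(float(state[eid])) for eid in readouts.ids):
            return level
    return None


def t_test_p_value(state: Marking, control: Marking, paired: bool = True,
                   log_scale: bool = False, floor: float = LOG_FLOOR) -> float:
    """Two-sided t-test p-value for concentration changes across components.

    Paired by default (the same components under two conditions); Welch's
    unpaired test behind ``paired=False``.  With ``log_scale`` the test runs
    on log10 concentrations floored at ``floor``, which bounds the influence
    of any single large pool (the screen uses this).  Identical markings
    give p = 1.
    """
    ids = sorted(state)
    if set(ids) != set(control):
        raise ValueError("state and control must cover the same components")
    if len(ids) < 2:
        raise ValueError("need at least 2 components")
    a = np.array([float(state[i]) for i in ids])
    b = np.array([float(control[i]) for i in ids])
    if log_scale:
        a = np.log10(np.maximum(a, floor))
        b = np.log10(np.maximum(b, floor))
    if np.array_equal(a, b):
        return 1.0
    if paired:
        d = a - b
        n = len(d)
        sd = d.std(ddof=1)
        if sd == 0.0:
            return float(np.finfo(float).tiny)
        t = d.mean() / (sd / math.sqrt(n))
        p = 2.0 * stats.t.sf(abs(t), n - 1)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
        p = float(p)
    return min(max(p, float(np.finfo(float).tiny)), 1.0)


def anti_mirna_screen(model: ModelNetwork,
                      anti_ids: Optional[Sequence[str]] = None,
                      dose_levels: Optional[Sequence[float]] = None,
                      readouts: Optional[ReadoutSet] = None,
                      cfg: KineticConfig = EXPERIMENT_CONFIG,
                      overexpression_level: float = OVEREXPRESSION_LEVEL,
                      mask_threshold: float = 0.001,
                      paired: bool = True,
                      log_scale: bool = True) -> ScreenResult:
    """Screen anti-miRNA inhibitors one at a time.

    For each anti-miRNA, the cognate miRNA is over-expressed alone; the
    control is the same over-expressed state with the inhibitor absent.  The
    heatmap reports log2 ratios of the readouts per dose versus that control;
    the p-value is a paired t-test over the concentration changes of all
    model components at the top dose.  Combination dosing is out of scope.
    """
    if anti_ids is None:
        anti_ids = sorted(e.id for e in model.entities.values()
                          if e.role is Role.PSEUDO_OBJECT)
    if not anti_ids:
        return ScreenResult(p_values=pd.Series(dtype=float))
    if dose_levels is None:
        dose_levels = (0.1, 1.0, 10.0,
                       SATURATING_DOSE_FACTOR * overexpression_level)
    dose_levels = tuple(float(x) for x in dose_levels)
    readouts = readouts or ReadoutSet.active_proteins(model)
    readouts.validate(model)

    baseline = control_state(model, cfg=cfg, no_mirnas=True)
    p_values: dict[str, float] = {}
    end_states: dict[str, Marking] = {}
    control_states: dict[str, Marking] = {}
    heat_rows: dict[tuple[str, float], pd.Series] = {}
    for anti in anti_ids:
        if anti not in model.entities:
            raise UnknownEntityError(f"anti-miRNA {anti!r} not in model")
        mirna = anti[len("anti-"):]
        base_overrides = _silenced(model, keep=mirna, level=overexpression_level)
        ctrl = steady_state(_with_clamps(model, {**base_overrides, anti: 0.0}),
                            cfg=cfg)
        control_states[anti] = ctrl
        state = ctrl
        for dose in dose_levels:
            state = steady_state(
                _with_clamps(model, {**base_overrides, anti: dose}), cfg=cfg)
            heat_rows[(anti, dose)] = log2_ratio(state, ctrl, readouts.ids)
        end_states[anti] = state  # top dose
        p_values[anti] = t_test_p_value(state, ctrl, paired=paired,
                                        log_scale=log_scale)

    heat = pd.DataFrame(heat_rows).T
    heat.index.names = ["anti_mirna", "dose_nM"]
    return ScreenResult(
        p_values=pd.Series(p_values).sort_index(),
        end_states=end_states,
        control_states=control_states,
        heatmap=HeatmapResult(heat, mask_threshold=mask_threshold),
        baseline=baseline,
        dose_levels=dose_levels,
    )


def rank_anti_mirnas(screen: ScreenResult, alpha: float = 0.05) -> pd.DataFrame:
    """Rank screened anti-miRNAs by ascending p-value (ties broken by id).

    Raw p-values drive the ranking, with ``significant`` flagging p < alpha;
    Benjamini-Hochberg adjusted values are reported in an extra column.
    """
    if screen.p_values.empty:
        return pd.DataFrame(columns=["anti_mirna", "p_value", "significant", "p_bh"])
    df = screen.p_values.rename("p_value").rename_axis("anti_mirna").reset_index()
    df = df.sort_values(["p_value", "anti_mirna"], kind="mergesort").reset_index(drop=True)
    df["significant"] = df["p_value"] < alpha
    n = len(df)
    bh = df["p_value"].to_numpy() * n / np.arange(1, n + 1)
    df["p_bh"] = np.minimum.accumulate(bh[::-1])[::-1].clip(max=1.0)
    return df


def target_count_histogram(table: TargetTable,
                           mirnas: Optional[Iterable[str]] = None
                           ) -> tuple[pd.Series, pd.Series]:
    """Distinct-target counts per miRNA and distinct-miRNA counts per target."""
    mirnas = list(mirnas) if mirnas is not None else table.mirnas()
    per_mirna = pd.Series(
        {m: len(set(table.targets_of(m))) for m in mirnas}, dtype=int)
    per_target: dict[str, set[str]] = {}
    for m, t, _ in table.rows:
        per_target.setdefault(t, set()).add(m)
    per_target_counts = pd.Series(
        {t: len(ms) for t, ms in sorted(per_target.items())}, dtype=int)
    return per_mirna, per_target_counts
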