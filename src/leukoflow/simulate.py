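"""Synthetic multi-tube bone-marrow cases with known ground truth.

Each population (lymphocyte subsets, monocytes, granulocytes, NRBCs,
leukemic blasts) is a template of five-level marker expressions plus
scatter parameters.  Fluorescence is Gaussian on the transformed
(arcsinh) scale — i.e. log-normal-like on the linear scale the FCS files
carry — and scatter is Gaussian on the linear scale.  Artifacts are
injected with exact bookkeeping: doublets are synthesized by pairing two
cells (FSC-A and fluorescence add, FSC-H takes the larger parent),
debris sits at low scatter with autofluorescence-level signal, and an
optional drift shifts FSC-A over a stated acquisition interval.

Cross-tube identity is simulated the way a real aliquoted sample behaves:
each population's backbone (CD45 + scatter) location is drawn once per
case and only jittered per tube, which is what makes cross-tube anchor
matching meaningful.

Everything is reproducible event-for-event from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError
from .fcs import ChannelMeta, EventTable, PanelConfig

__all__ = [
    "LEVEL_MEANS",
    "PopulationTemplate",
    "DriftSpec",
    "CaseTruth",
    "default_panel",
    "builtin_templates",
    "simulate_case",
    "simulate_cohort",
]

# transformed-scale (arcsinh, cofactor 150) location of each expression level
LEVEL_MEANS = {"negative": 0.3, "dim": 1.6, "partial": 2.7, "positive": 4.0, "bright": 5.5}
DEFAULT_LEVEL_SD = 0.35
COFACTOR = 150.0

BACKBONE = ("CD45",)


def default_panel() -> PanelConfig:
    """Four-tube 8-color acute-leukemia screening panel (CD45 backbone)."""
    return PanelConfig(
        tubes={
            "tube1": ["CD45", "CD19", "CD10", "CD20", "CD22", "CD34", "CD38", "HLA-DR"],
            "tube2": ["CD45", "CD3", "CD5", "CD7", "CD2", "CD4", "CD8", "CD56"],
            "tube3": ["CD45", "CD13", "CD33", "CD117", "CD34", "CD14", "CD64", "CD16"],
            "tube4": ["CD45", "MPO", "cCD3", "CD79a", "CD34", "CD19", "CD7", "CD117"],
        },
        backbone_markers=["CD45"],
    )


@dataclass
class PopulationTemplate:
    name: str
    category: str                        # truth cell category
    fraction: float
    levels: dict[str, str] = field(default_factory=dict)   # marker -> level name
    fsc_mean: float = 50000.0
    fsc_sd: float = 7000.0
    ssc_mean: float = 15000.0
    ssc_sd: float = 3000.0
    level_sd: float = DEFAULT_LEVEL_SD

    def __post_init__(self) -> None:
        if self.fraction <= 0:
            raise ConfigurationError(f"population {self.name}: fraction must be > 0")
        if self.fsc_sd <= 0 or self.ssc_sd <= 0 or self.level_sd <= 0:
            raise ConfigurationError(f"population {self.name}: sds must be > 0")
        unknown = [lv for lv in self.levels.values() if lv not in LEVEL_MEANS]
        if unknown:
            raise ConfigurationError(f"population {self.name}: unknown levels {unknown}")

    def level_mean(self, marker: str) -> float:
        return LEVEL_MEANS[self.levels.get(marker, "negative")]


@dataclass
class DriftSpec:
    """FSC-A shift over a fraction of the acquisition (defaults: middle third)."""

    start: float = 1 / 3
    end: float = 2 / 3
    magnitude_sd: float = 10.0           # shift in units of the event FSC-A SD


@dataclass
class CaseTruth:
    population_labels: dict[str, np.ndarray]   # tube -> per-event category
    artifact_labels: dict[str, np.ndarray]     # tube -> singlet|doublet|debris
    diagnosis: str
    blast_fraction: float                       # blasts / nucleated singlets
    seed: int


# ---------------------------------------------------------------------------
# Built-in template sets
# ---------------------------------------------------------------------------

def _normal_populations() -> list[PopulationTemplate]:
    return [
        PopulationTemplate(
            "granulocytes", "granulocyte", 0.50,
            {"CD45": "positive", "CD13": "positive", "CD33": "positive",
             "CD16": "positive", "CD64": "dim", "MPO": "positive"},
            fsc_mean=65000, fsc_sd=9000, ssc_mean=75000, ssc_sd=12000),
        PopulationTemplate(
            "T cells", "T_cell", 0.15,
            {"CD45": "bright", "CD3": "positive", "CD5": "positive",
             "CD7": "positive", "CD2": "positive", "CD4": "partial",
             "CD8": "partial", "cCD3": "positive"},
            fsc_mean=50000, fsc_sd=7000, ssc_mean=14000, ssc_sd=3000),
        PopulationTemplate(
            "B cells", "B_cell", 0.07,
            {"CD45": "bright", "CD19": "positive", "CD20": "positive",
             "CD22": "positive", "CD79a": "positive", "HLA-DR": "positive"},
            fsc_mean=50000, fsc_sd=7000, ssc_mean=14000, ssc_sd=3000),
        PopulationTemplate(
            "NK cells", "NK_cell", 0.05,
            {"CD45": "bright", "CD56": "positive", "CD7": "positive",
             "CD2": "positive", "CD16": "partial"},
            fsc_mean=52000, fsc_sd=7000, ssc_mean=16000, ssc_sd=3500),
        PopulationTemplate(
            "monocytes", "monocyte", 0.10,
            {"CD45": "positive", "CD14": "positive", "CD64": "positive",
             "CD33": "bright", "CD13": "positive", "HLA-DR": "positive",
             "CD4": "dim"},
            fsc_mean=75000, fsc_sd=9000, ssc_mean=35000, ssc_sd=6000),
        PopulationTemplate(
            "NRBCs", "NRBC", 0.13, {},
            fsc_mean=35000, fsc_sd=6000, ssc_mean=7000, ssc_sd=2000),
    ]


_BLAST_SCATTER = dict(fsc_mean=60000, fsc_sd=8000, ssc_mean=18000, ssc_sd=4000)

_BLAST_PHENOTYPES: dict[str, tuple[str, dict[str, str]]] = {
    # template set name -> (true diagnosis, blast marker levels)
    "AML_typical": ("AML", {
        "CD45": "dim", "CD34": "positive", "CD117": "positive",
        "CD13": "positive", "CD33": "positive", "HLA-DR": "positive",
        "MPO": "positive", "CD38": "positive"}),
    "B_ALL_typical": ("B_ALL", {
        "CD45": "dim", "CD19": "positive", "CD10": "positive",
        "CD34": "positive", "CD22": "positive", "CD38": "bright",
        "HLA-DR": "positive", "CD79a": "positive"}),
    "T_ALL_typical": ("T_ALL", {
        "CD45": "dim", "CD7": "positive", "CD5": "positive", "CD2": "positive",
        "cCD3": "positive", "CD34": "partial", "CD38": "positive",
        "CD10": "partial"}),
    # hard cases mirroring real-world review prompts: MPO-negative myeloid
    # blasts cross-expressing lymphoid antigens, and dim lineage markers
    "AML_aberrant_CD7": ("Abnormal_review", {
        "CD45": "dim", "CD34": "positive", "CD117": "positive",
        "CD13": "positive", "CD33": "positive", "HLA-DR": "positive",
        "MPO": "negative", "CD7": "positive", "CD56": "positive",
        "CD38": "positive"}),
    "T_ALL_dim_cCD3": ("Abnormal_review", {
        "CD45": "dim", "CD7": "positive", "CD5": "positive",
        "cCD3": "dim", "CD13": "positive", "CD34": "partial",
        "CD38": "positive"}),
}


def builtin_templates(blast_fraction: float = 0.5) -> dict[str, list[PopulationTemplate]]:
    """Named template sets: normal marrow plus typical and aberrant leukemias.

    Leukemic sets carry a blast population at ``blast_fraction`` with the
    residual normal compartments scaled down proportionally.
    """
    if not 0 < blast_fraction < 1:
        raise ConfigurationError("blast_fraction must be in (0, 1)")
    sets: dict[str, list[PopulationTemplate]] = {"normal_marrow": _normal_populations()}
    for name, (_, levels) in _BLAST_PHENOTYPES.items():
        residual = [replace(t, fraction=t.fraction * (1 - blast_fraction))
                    for t in _normal_populations()]
        category = {"B_ALL": "blast_B", "T_ALL": "blast_T"}.get(
            _BLAST_PHENOTYPES[name][0], "blast_myeloid")
        if name.startswith("T_ALL"):
            category = "blast_T"
        blast = PopulationTemplate(
            "blasts", category, blast_fraction, dict(levels), **_BLAST_SCATTER)
        sets[name] = [blast] + residual
    return sets


def template_diagnosis(set_name: str) -> str:
    """True diagnosis label of a built-in template set."""
    if set_name == "normal_marrow":
        return "Normal"
    return _BLAST_PHENOTYPES[set_name][0]


# ---------------------------------------------------------------------------
# Case simulation
# ---------------------------------------------------------------------------

def _tube_channels(markers: list[str]) -> list[ChannelMeta]:
    chans = [
        ChannelMeta("FSC-A", is_scatter=True),
        ChannelMeta("FSC-H", is_scatter=True),
        ChannelMeta("SSC-A", is_scatter=True),
        ChannelMeta("Time", is_time=True),
    ]
    for i, m in enumerate(markers, start=1):
        chans.append(ChannelMeta(f"FL{i}-A", marker=m))
    return chans


def simulate_case(
    templates: list[PopulationTemplate],
    n_events: int = 20000,
    panel: PanelConfig | None = None,
    doublet_frac: float = 0.0,
    debris_frac: float = 0.0,
    drift: DriftSpec | None = None,
    seed: int = 0,
    diagnosis: str = "",
) -> tuple[dict[str, EventTable], CaseTruth]:
    """Generate one multi-tube case with exact truth bookkeeping.

    Per tube: floor(doublet_frac * n) doublets and floor(debris_frac * n)
    debris events; the remainder are nucleated singlets drawn from the
    population templates by a multinomial split.  Raw (linear-scale)
    EventTables are returned, one per tube, alongside the truth.
    """
    panel = panel or default_panel()
    total = sum(t.fraction for t in templates)
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ConfigurationError(f"template fractions sum to {total:.4f}, expected 1")
    if not (0 <= doublet_frac < 0.5 and 0 <= debris_frac < 0.5):
        raise ConfigurationError("artifact fractions must be in [0, 0.5)")
    rng = np.random.default_rng(seed)

    n_doublet = int(np.floor(doublet_frac * n_events))
    n_debris = int(np.floor(debris_frac * n_events))
    n_singlet = n_events - n_doublet - n_debris
    fracs = np.array([t.fraction for t in templates])
    pop_counts = rng.multinomial(n_singlet, fracs / fracs.sum())

    # case-level population offsets, shared across tubes (aliquots of one marrow)
    case_scatter_shift = {
        t.name: (rng.normal(0, 0.1 * t.fsc_sd), rng.normal(0, 0.1 * t.ssc_sd))
        for t in templates
    }
    case_marker_shift = {
        (t.name, m): rng.normal(0, 0.1 * t.level_sd)
        for t in templates
        for tube_markers in panel.tubes.values()
        for m in tube_markers
    }

    tables: dict[str, EventTable] = {}
    pop_labels: dict[str, np.ndarray] = {}
    art_labels: dict[str, np.ndarray] = {}
    blast_count = int(sum(c for t, c in zip(templates, pop_counts)
                          if t.category.startswith("blast")))

    for tube_id, markers in panel.tubes.items():
        chans = _tube_channels(markers)
        cols = {c.short_name if not c.marker else c.marker: i
                for i, c in enumerate(chans)}
        n_chan = len(chans)

        # --- nucleated singlets -------------------------------------------
        rows = np.empty((n_singlet, n_chan))
        labels = np.empty(n_singlet, dtype=object)
        start = 0
        for t, cnt in zip(templates, pop_counts):
            if cnt == 0:
                continue
            sl = slice(start, start + cnt)
            dfsc, dssc = case_scatter_shift[t.name]
            fsc = rng.normal(t.fsc_mean + dfsc, t.fsc_sd, cnt)
            fsc = np.clip(fsc, 1.0, None)
            ssc = np.clip(rng.normal(t.ssc_mean + dssc, t.ssc_sd, cnt), 1.0, None)
            rows[sl, cols["FSC-A"]] = fsc
            rows[sl, cols["FSC-H"]] = np.clip(
                0.95 * fsc + rng.normal(0, 0.02 * t.fsc_mean, cnt), 1.0, None)
            rows[sl, cols["SSC-A"]] = ssc
            for m in markers:
                y = rng.normal(t.level_mean(m) + case_marker_shift[(t.name, m)],
                               t.level_sd, cnt)
                rows[sl, cols[m]] = np.sinh(y) * COFACTOR
            labels[sl] = t.category
            start += cnt

        # --- doublets: two singlets measured as one event ------------------
        if n_doublet:
            i1 = rng.integers(0, n_singlet, n_doublet)
            i2 = rng.integers(0, n_singlet, n_doublet)
            drows = rows[i1] + rows[i2]                      # areas/fluorescence add
            drows[:, cols["FSC-H"]] = np.maximum(
                rows[i1, cols["FSC-H"]], rows[i2, cols["FSC-H"]])
            dlabels = labels[i1]
        else:
            drows = np.empty((0, n_chan))
            dlabels = np.empty(0, dtype=object)

        # --- debris: low scatter, autofluorescence-level signal ------------
        if n_debris:
            brows = np.empty((n_debris, n_chan))
            bfsc = np.clip(rng.normal(5000, 1500, n_debris), 200.0, None)
            brows[:, cols["FSC-A"]] = bfsc
            brows[:, cols["FSC-H"]] = np.clip(
                0.95 * bfsc + rng.normal(0, 300, n_debris), 100.0, None)
            brows[:, cols["SSC-A"]] = np.clip(
                rng.normal(3000, 1000, n_debris), 100.0, None)
            for m in markers:
                brows[:, cols[m]] = np.sinh(rng.normal(0.1, 0.2, n_debris)) * COFACTOR
        else:
            brows = np.empty((0, n_chan))

        values = np.vstack([rows, drows, brows])
        art = np.concatenate([
            np.full(n_singlet, "singlet", dtype=object),
            np.full(n_doublet, "doublet", dtype=object),
            np.full(n_debris, "debris", dtype=object),
        ])
        pop = np.concatenate([labels, dlabels,
                              np.full(n_debris, "debris", dtype=object)])

        # interleave in acquisition time
        order = rng.permutation(n_events)
        values, art, pop = values[order], art[order], pop[order]
        values[:, cols["Time"]] = np.arange(n_events, dtype=float)

        if drift is not None:
            t0, t1 = int(drift.start * n_events), int(drift.end * n_events)
            sd = values[:, cols["FSC-A"]].std()
            values[t0:t1, cols["FSC-A"]] += drift.magnitude_sd * sd

        tables[tube_id] = EventTable(values=values, channels=chans,
                                     tube_id=tube_id, transform_state="raw")
        pop_labels[tube_id] = pop
        art_labels[tube_id] = art

    truth = CaseTruth(
        population_labels=pop_labels,
        artifact_labels=art_labels,
        diagnosis=diagnosis,
        blast_fraction=blast_count / n_singlet if n_singlet else 0.0,
        seed=seed,
    )
    return tables, truth


DEFAULT_COHORT_MIX = {"AML": 138 / 294, "B_ALL": 53 / 294,
                      "T_ALL": 9 / 294, "Normal": 94 / 294}

_MIX_TEMPLATE = {"AML": "AML_typical", "B_ALL": "B_ALL_typical",
                 "T_ALL": "T_ALL_typical", "Normal": "normal_marrow"}


def simulate_cohort(
    n_cases: int,
    mix: dict[str, float] | None = None,
    seed: int = 0,
    n_events: int = 20000,
    doublet_frac: float = 0.0,
    debris_frac: float = 0.0,
    blast_fraction_range: tuple[float, float] = (0.3, 0.7),
):
    """Yield (case_id, tables, truth) for a cohort with a fixed class mix.

    Case counts per diagnosis follow largest-remainder rounding of the mix
    (echoing the class balance of a clinical acute-leukemia caseload);
    per-case seeds derive from the cohort seed, and leukemic cases draw
    their blast fraction uniformly from ``blast_fraction_range``.
    """
    mix = dict(mix or DEFAULT_COHORT_MIX)
    total = sum(mix.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ConfigurationError(f"mix proportions sum to {total:.4f}, expected 1")
    raw = {k: n_cases * v for k, v in mix.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n_cases - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    rng = np.random.default_rng(seed)
    plan = [dx for dx in sorted(counts) for _ in range(counts[dx])]
    for i, dx in enumerate(plan):
        case_seed = int(rng.integers(0, 2**31 - 1))
        bf = float(rng.uniform(*blast_fraction_range))
        tmpl_name = _MIX_TEMPLATE.get(dx, dx)
        templates = builtin_templates(blast_fraction=bf)[tmpl_name]
        truth_dx = template_diagnosis(tmpl_name)
        tables, truth = simulate_case(
            templates, n_events=n_events, doublet_frac=doublet_frac,
            debris_frac=debris_frac, seed=case_seed, diagnosis=truth_dx)
        yield f"case{i:03d}", tables, truth
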