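"""Synthetic cohort pairs and target libraries with known ground truth.

The generator emulates the statistical structure the pipeline assumes: two
cohorts per disease sharing a planted direction-concordant gene program,
cohort-specific distractors (planted in one cohort only), within-disease
discordant genes (opposite signs in the two cohorts), optional genes shared
between the two diseases (concordant or discordant across diseases), and a
GMT target library in which designated "hub" miRNA regulons are enriched
for a planted program at a stated enrichment factor rho.

Per-sample expression for each gene is drawn Normal(mu_group, sigma); the
per-gene summary statistics are then computed exactly as a differential
expression analysis would: log2FC as the group-mean difference, p from a
Welch two-sample t statistic, FDR by BH within each cohort.  This keeps
(log2fc, p, fdr) triples internally consistent, which pure marginal
sampling would not.  A weak cohort regime (noise_scale > 1) inflates
within-group variance so that few genes survive multiple testing — the
situation motivating the vote-based consensus rule.  All randomness flows
through one generator seeded from the spec, so a seed fully reproduces
every table and the library.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import ConsensusSignature, SignaturePartition
from .errors import ConfigError
from .ora import P_FLOOR, bh_adjust
from .toptable_io import DETable, from_frame
from .target_library import TargetLibrary

logger = logging.getLogger(__name__)

ROLE_PROGRAM = "program"
ROLE_DISTRACTOR_C1 = "distractor_cohort1"
ROLE_DISTRACTOR_C2 = "distractor_cohort2"
ROLE_DISCORDANT = "discordant"
ROLE_SHARED_CONCORDANT = "shared_concordant"
ROLE_SHARED_DISCORDANT = "shared_discordant"

_CONCORDANT_ROLES = {ROLE_PROGRAM, ROLE_SHARED_CONCORDANT, ROLE_SHARED_DISCORDANT}


@dataclass(frozen=True)
class CohortDesign:
    """Sample sizes and noise regime of one cohort.

    ``noise_scale`` multiplies the base within-group SD; values > 1 emulate
    a weak (low-power) cohort, values < 1 a high-SNR one.
    """

    n_cases: int
    n_controls: int
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cases < 2 or self.n_controls < 2:
            raise ConfigError("each arm needs >= 2 samples for a t statistic")
        if self.noise_scale < 0:
            raise ConfigError("noise_scale must be >= 0")


@dataclass(frozen=True)
class DiseaseDesign:
    """Planted structure for one disease's cohort pair."""

    name: str
    cohorts: tuple[CohortDesign, CohortDesign]
    n_program_up: int = 50
    n_program_down: int = 50
    n_distractor: int = 20
    n_discordant: int = 10

    @property
    def n_planted(self) -> int:
        return (self.n_program_up + self.n_program_down
                + self.n_distractor + self.n_discordant)


@dataclass(frozen=True)
class HubDesign:
    """A planted hub regulon enriched for one disease's program genes.

    ``rho`` is the enrichment factor: within-regulon program density over
    the background program density (|program| / n_genes).
    """

    mirna: str
    regulon_size: int
    program: tuple[str, str]  # (disease name, "up" | "down")
    rho: float = 4.0


@dataclass(frozen=True)
class LibraryDesign:
    n_mirnas: int = 60
    regulon_size_range: tuple[int, int] = (20, 60)
    hubs: tuple[HubDesign, ...] = ()


@dataclass(frozen=True)
class SyntheticSpec:
    """Full specification of a synthetic study; the seed fixes everything."""

    n_genes: int
    diseases: tuple[DiseaseDesign, ...]
    library: LibraryDesign = field(default_factory=LibraryDesign)
    n_shared_concordant: int = 0
    n_shared_discordant: int = 0
    effect_mean: float = 3.0
    effect_sd: float = 0.5
    effect_floor: float = 1.0
    null_sd: float = 0.15
    sample_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        if not self.diseases:
            raise ConfigError("at least one disease design required")
        n_shared = self.n_shared_concordant + self.n_shared_discordant
        if n_shared > 0 and len(self.diseases) < 2:
            raise ConfigError("shared genes require two diseases")
        total = n_shared + sum(d.n_planted for d in self.diseases)
        if total > self.n_genes:
            raise ConfigError(
                f"planted counts ({total}) exceed n_genes ({self.n_genes})"
            )
        lo, hi = self.library.regulon_size_range
        if not (1 <= lo <= hi):
            raise ConfigError("invalid regulon_size_range")
        if hi > self.n_genes:
            raise ConfigError("regulon size range exceeds universe")
        for hub in self.library.hubs:
            if hub.regulon_size > self.n_genes:
                raise ConfigError(f"hub {hub.mirna}: regulon exceeds universe")
            if hub.rho <= 0:
                raise ConfigError(f"hub {hub.mirna}: rho must be positive")
        for v in (self.effect_mean, self.effect_sd, self.null_sd,
                  self.sample_sd, self.effect_floor):
            if v < 0:
                raise ConfigError("effect/noise parameters must be >= 0")


class TruthTable:
    """Planted roles and directions, one row per (disease, planted gene)."""

    COLUMNS = ("symbol", "disease", "role",
               "direction_cohort1", "direction_cohort2", "effect")

    def __init__(self, df: pd.DataFrame, universe: tuple[str, ...]):
        self.df = df.reset_index(drop=True)
        self.universe = universe

    def for_disease(self, disease: str) -> "TruthTable":
        return TruthTable(
            self.df.loc[self.df["disease"] == disease], self.universe
        )

    def concordant_program(self, disease: str) -> dict[str, str]:
        """Genes planted concordantly in both cohorts of ``disease``
        (the expected strict-consensus membership), symbol -> direction."""
        sub = self.df[(self.df["disease"] == disease)
                      & self.df["role"].isin(_CONCORDANT_ROLES)]
        return dict(zip(sub["symbol"], sub["direction_cohort1"]))

    def program_symbols(self, disease: str, direction: str | None = None
                        ) -> frozenset[str]:
        """Disease-specific program genes (excludes shared plantings)."""
        sub = self.df[(self.df["disease"] == disease)
                      & (self.df["role"] == ROLE_PROGRAM)]
        if direction is not None:
            sub = sub[sub["direction_cohort1"] == direction]
        return frozenset(sub["symbol"])

    def shared_sets(self) -> tuple[dict[str, str], dict[str, tuple[str, str]]]:
        """(concordant symbol->direction, discordant symbol->(dirA, dirB))."""
        conc = self.df[self.df["role"] == ROLE_SHARED_CONCORDANT]
        disc = self.df[self.df["role"] == ROLE_SHARED_DISCORDANT]
        concordant = dict(zip(
            conc.drop_duplicates("symbol")["symbol"],
            conc.drop_duplicates("symbol")["direction_cohort1"],
        ))
        discordant: dict[str, tuple[str, str]] = {}
        for sym, grp in disc.groupby("symbol"):
            grp = grp.sort_values("disease")
            dirs = tuple(grp["direction_cohort1"])
            if len(dirs) == 2:
                discordant[sym] = (dirs[0], dirs[1])
        return concordant, discordant

    def to_csv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass
class StudyData:
    """Everything one synthetic study produced."""

    spec: SyntheticSpec
    tables: dict[str, tuple[DETable, DETable]]
    truth: TruthTable


def _magnitudes(rng: np.random.Generator, n: int, spec: SyntheticSpec
                ) -> np.ndarray:
    return np.maximum(spec.effect_floor,
                      rng.normal(spec.effect_mean, spec.effect_sd, n))


def _signs(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice([-1.0, 1.0], size=n)


def _dir(sign: float) -> str:
    return "up" if sign > 0 else "down"


def generate_study(spec: SyntheticSpec) -> StudyData:
    """Generate all cohort tables and the truth table for a spec."""
    rng = np.random.default_rng(spec.seed)
    width = max(5, len(str(spec.n_genes)))
    symbols = np.array([f"SG{i + 1:0{width}d}" for i in range(spec.n_genes)])
    pool = rng.permutation(spec.n_genes)
    cursor = 0

    def take(n: int) -> np.ndarray:
        nonlocal cursor
        idx = pool[cursor:cursor + n]
        cursor += n
        return idx

    # ---- role assignment -------------------------------------------------
    # deltas[disease][cohort] = true signed effect per gene
    deltas: dict[str, list[np.ndarray]] = {
        d.name: [np.zeros(spec.n_genes), np.zeros(spec.n_genes)]
        for d in spec.diseases
    }
    truth_rows: list[dict] = []

    def plant(disease: str, idx: np.ndarray, role: str,
              sign_c1: np.ndarray, sign_c2: np.ndarray,
              mags: np.ndarray, cohorts=(0, 1)) -> None:
        for j, gi in enumerate(idx):
            if 0 in cohorts:
                deltas[disease][0][gi] = sign_c1[j] * mags[j]
            if 1 in cohorts:
                deltas[disease][1][gi] = sign_c2[j] * mags[j]
            truth_rows.append({
                "symbol": symbols[gi],
                "disease": disease,
                "role": role,
                "direction_cohort1": _dir(sign_c1[j]) if 0 in cohorts else "",
                "direction_cohort2": _dir(sign_c2[j]) if 1 in cohorts else "",
                "effect": mags[j],
            })

    if len(spec.diseases) >= 2:
        d_a, d_b = spec.diseases[0].name, spec.diseases[1].name
        # shared concordant: same direction in both diseases, both cohorts
        idx = take(spec.n_shared_concordant)
        signs = _signs(rng, len(idx))
        for dz in (d_a, d_b):
            plant(dz, idx, ROLE_SHARED_CONCORDANT, signs, signs,
                  _magnitudes(rng, len(idx), spec))
        # shared discordant: up in disease A <-> down in disease B (or vice versa)
        idx = take(spec.n_shared_discordant)
        signs = _signs(rng, len(idx))
        plant(d_a, idx, ROLE_SHARED_DISCORDANT, signs, signs,
              _magnitudes(rng, len(idx), spec))
        plant(d_b, idx, ROLE_SHARED_DISCORDANT, -signs, -signs,
              _magnitudes(rng, len(idx), spec))

    for dz in spec.diseases:
        up_idx = take(dz.n_program_up)
        plant(dz.name, up_idx, ROLE_PROGRAM,
              np.ones(len(up_idx)), np.ones(len(up_idx)),
              _magnitudes(rng, len(up_idx), spec))
        down_idx = take(dz.n_program_down)
        plant(dz.name, down_idx, ROLE_PROGRAM,
              -np.ones(len(down_idx)), -np.ones(len(down_idx)),
              _magnitudes(rng, len(down_idx), spec))
        n_d1 = dz.n_distractor // 2
        n_d2 = dz.n_distractor - n_d1
        idx = take(n_d1)
        s = _signs(rng, n_d1)
        plant(dz.name, idx, ROLE_DISTRACTOR_C1, s, s,
              _magnitudes(rng, n_d1, spec), cohorts=(0,))
        idx = take(n_d2)
        s = _signs(rng, n_d2)
        plant(dz.name, idx, ROLE_DISTRACTOR_C2, s, s,
              _magnitudes(rng, n_d2, spec), cohorts=(1,))
        idx = take(dz.n_discordant)
        s = _signs(rng, dz.n_discordant)
        plant(dz.name, idx, ROLE_DISCORDANT, s, -s,
              _magnitudes(rng, dz.n_discordant, spec))

    truth = TruthTable(
        pd.DataFrame(truth_rows, columns=list(TruthTable.COLUMNS)),
        universe=tuple(symbols),
    )

    # ---- per-cohort sampling --------------------------------------------
    tables: dict[str, tuple[DETable, DETable]] = {}
    for dz in spec.diseases:
        pair = []
        for ci, cohort in enumerate(dz.cohorts):
            delta = deltas[dz.name][ci] + rng.normal(
                0.0, spec.null_sd, spec.n_genes
            ) * (deltas[dz.name][ci] == 0)
            sigma = spec.sample_sd * cohort.noise_scale
            cases = rng.normal(delta[:, None], sigma,
                               (spec.n_genes, cohort.n_cases))
            ctrls = rng.normal(0.0, sigma,
                               (spec.n_genes, cohort.n_controls))
            lfc = cases.mean(axis=1) - ctrls.mean(axis=1)
            import warnings as _warnings
            with np.errstate(divide="ignore", invalid="ignore"), \
                    _warnings.catch_warnings():
                # zero-variance arms are expected in the zero-noise limit
                _warnings.simplefilter("ignore", RuntimeWarning)
                res = stats.ttest_ind(cases, ctrls, axis=1, equal_var=False)
                pvals = np.asarray(res.pvalue, dtype=float)
            degenerate = ~np.isfinite(pvals)  # zero variance in both arms
            pvals[degenerate] = np.where(lfc[degenerate] == 0, 1.0, P_FLOOR)
            pvals = np.clip(pvals, P_FLOOR, 1.0)
            fdr = bh_adjust(pvals)
            df = pd.DataFrame({
                "symbol": symbols,
                "log2fc": lfc,
                "pvalue": pvals,
                "fdr": np.clip(fdr, P_FLOOR, 1.0),
            })
            pair.append(from_frame(
                df,
                dataset_id=f"{dz.name}_cohort{ci + 1}",
                disease=dz.name,
                provenance={"source": "synthetic", "seed": spec.seed,
                            "noise_scale": cohort.noise_scale},
            ))
        tables[dz.name] = (pair[0], pair[1])
    return StudyData(spec=spec, tables=tables, truth=truth)


def generate_cohort_pair(
    spec: SyntheticSpec, disease: str
) -> tuple[DETable, DETable, TruthTable]:
    """One disease's cohort pair plus its slice of the truth table."""
    study = generate_study(spec)
    if disease not in study.tables:
        raise ConfigError(f"unknown disease {disease!r}")
    t1, t2 = study.tables[disease]
    return t1, t2, study.truth.for_disease(disease)


def generate_target_library(
    spec: SyntheticSpec, truth: TruthTable
) -> tuple[TargetLibrary, pd.DataFrame]:
    """Background regulons plus planted hubs, with a hub manifest.

    Background regulons are uniform draws from the universe at sizes in the
    configured range.  Each hub draws ``round(min(1, rho * density) * K)``
    of its K targets from its designated program (density = |program| /
    n_genes) and the rest from outside it; the manifest records the
    realized program overlap per hub.
    """
    rng = np.random.default_rng([spec.seed, 104729])
    universe = np.array(truth.universe)
    lo, hi = spec.library.regulon_size_range

    regulons: dict[str, frozenset[str]] = {}
    manifest_rows = []
    for hub in spec.library.hubs:
        disease, direction = hub.program
        program = sorted(truth.program_symbols(disease, direction))
        if not program:
            raise ConfigError(
                f"hub {hub.mirna}: no planted program for {hub.program}"
            )
        density = len(program) / spec.n_genes
        frac = min(1.0, hub.rho * density)
        n_prog = min(len(program), int(np.floor(frac * hub.regulon_size + 0.5)))
        prog_members = rng.choice(program, size=n_prog, replace=False)
        others = np.setdiff1d(universe, np.array(program))
        rest = rng.choice(others, size=hub.regulon_size - n_prog, replace=False)
        regulons[hub.mirna] = frozenset(prog_members) | frozenset(rest)
        manifest_rows.append({
            "mirna": hub.mirna,
            "regulon_size": hub.regulon_size,
            "n_program_targets": n_prog,
            "program_disease": disease,
            "program_direction": direction,
            "rho_requested": hub.rho,
            "rho_realized": (n_prog / hub.regulon_size) / density,
        })

    n_background = spec.library.n_mirnas - len(spec.library.hubs)
    for i in range(n_background):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        regulons[f"hsa-miR-B{i + 1:03d}-5p"] = frozenset(members)

    manifest = pd.DataFrame(
        manifest_rows,
        columns=["mirna", "regulon_size", "n_program_targets",
                 "program_disease", "program_direction",
                 "rho_requested", "rho_realized"],
    )
    return TargetLibrary(regulons=regulons, source="synthetic"), manifest


# ---- truth-recovery instrumentation -------------------------------------

def consensus_recovery(
    signature: ConsensusSignature, truth: TruthTable, disease: str
) -> dict[str, float]:
    """Precision/recall of a consensus signature against the planted
    concordant program (direction must match to count as a true positive)."""
    expected = truth.concordant_program(disease)
    called = {s: g.direction for s, g in signature.members.items()}
    tp = sum(1 for s, d in called.items() if expected.get(s) == d)
    precision = tp / len(called) if called else (1.0 if not expected else 0.0)
    recall = tp / len(expected) if expected else 1.0
    return {"precision": precision, "recall": recall,
            "n_called": float(len(called)), "n_true": float(len(expected))}


def partition_recovery(
    partition: SignaturePartition, truth: TruthTable
) -> dict[str, float]:
    """Agreement of the shared partition parts with the planted shared sets."""
    conc_true, disc_true = truth.shared_sets()

    def prf(called: set, expected: set) -> tuple[float, float]:
        tp = len(called & expected)
        precision = tp / len(called) if called else (1.0 if not expected else 0.0)
        recall = tp / len(expected) if expected else 1.0
        return precision, recall

    cp, cr = prf(set(partition.shared_concordant), set(conc_true))
    dp, dr = prf(set(partition.shared_discordant), set(disc_true))
    return {
        "shared_concordant_precision": cp, "shared_concordant_recall": cr,
        "shared_discordant_precision": dp, "shared_discordant_recall": dr,
    }


def fdr_rank(results: pd.DataFrame, mirna: str) -> int | None:
    """1-based rank of a miRNA in a ranked enrichment table (None if absent)."""
    pos = results.index[results["mirna"] == mirna]
    return int(pos[0]) + 1 if len(pos) else None


def degree_rank(hub_table: pd.DataFrame, mirna: str) -> int | None:
    """1-based degree rank of a miRNA in a hub table (None if absent)."""
    pos = hub_table.index[hub_table["id"] == mirna]
    return int(hub_table.loc[pos[0], "rank"]) if len(pos) else None


def truth_recovery_report(
    consensus_by_disease: Mapping[str, ConsensusSignature],
    partition: SignaturePartition | None,
    truth: TruthTable,
    hub_ranks: Mapping[str, int | None] | None = None,
) -> dict[str, dict]:
    """Per-stage precision/recall report for a synthetic run."""
    report: dict[str, dict] = {
        f"consensus_{dz}": consensus_recovery(sig, truth, dz)
        for dz, sig in consensus_by_disease.items()
    }
    if partition is not None:
        report["partition"] = partition_recovery(partition, truth)
    if hub_ranks is not None:
        report["hub_ranks"] = {m: (int(r) if r is not None else None)
                               for m, r in hub_ranks.items()}
    return report


def hub_replicate_spec(seed: int = 0) -> SyntheticSpec:
    """Benchmark preset for planted-hub recovery replicates.

    One well-powered disease (two 20-vs-20 cohorts) with a 120-gene program
    and a 60-regulon library whose single hub draws its targets from the
    up-program at enrichment factor rho = 5 — comfortably inside the regime
    (rho >= 4, regulon >= 30, program >= 50) where the hub is expected to
    dominate both enrichment and network degree.
    """
    return SyntheticSpec(
        n_genes=2000,
        diseases=(DiseaseDesign(
            name="D",
            cohorts=(CohortDesign(20, 20, 1.0), CohortDesign(20, 20, 1.0)),
            n_program_up=60, n_program_down=60,
            n_distractor=20, n_discordant=10,
        ),),
        library=LibraryDesign(
            n_mirnas=60,
            regulon_size_range=(20, 60),
            hubs=(HubDesign("hsa-miR-HUB-5p", 50, ("D", "up"), rho=5.0),),
        ),
        seed=seed,
    )


def weak_cohort_spec(seed: int = 0) -> SyntheticSpec:
    """Benchmark preset for the vote-vs-strict recall comparison.

    One adequately powered cohort (10 vs 5) paired with a weak cohort
    (8 vs 8, within-group SD inflated x4) — the regime in which strict
    intersection starves while the vote rule retains direction-consistent
    genes supported by the stronger cohort.
    """
    return SyntheticSpec(
        n_genes=2000,
        diseases=(DiseaseDesign(
            name="D",
            cohorts=(CohortDesign(10, 5, 1.0), CohortDesign(8, 8, 4.0)),
            n_program_up=40, n_program_down=40,
            n_distractor=20, n_discordant=10,
        ),),
        library=LibraryDesign(n_mirnas=20, regulon_size_range=(20, 60)),
        seed=seed,
    )


def default_spec(seed: int = 0) -> SyntheticSpec:
    """The default study preset.

    Mirrors the cohort shapes of the motivating study design: a large
    case/control pair and a tiny high-SNR pair for the first disease
    (strict-rule regime), and a modest pair plus a variance-inflated weak
    cohort for the second (vote-rule regime), with a small shared gene set
    of which most members are discordant between the diseases.
    """
    return SyntheticSpec(
        n_genes=4000,
        diseases=(
            DiseaseDesign(
                name="CLL",
                cohorts=(CohortDesign(179, 33, 1.0), CohortDesign(5, 2, 0.05)),
                n_program_up=150, n_program_down=150,
                n_distractor=60, n_discordant=20,
            ),
            DiseaseDesign(
                name="MM",
                cohorts=(CohortDesign(10, 5, 1.0), CohortDesign(8, 8, 4.0)),
                n_program_up=25, n_program_down=25,
                n_distractor=30, n_discordant=10,
            ),
        ),
        library=LibraryDesign(
            n_mirnas=80,
            regulon_size_range=(20, 60),
            hubs=(
                HubDesign("hsa-miR-H001-5p", 60, ("CLL", "up"), rho=5.0),
                HubDesign("hsa-miR-H002-3p", 50, ("CLL", "down"), rho=4.0),
                HubDesign("hsa-miR-H003-5p", 20, ("MM", "down"), rho=6.0),
            ),
        ),
        n_shared_concordant=2,
        n_shared_discordant=3,
        seed=seed,
    )
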