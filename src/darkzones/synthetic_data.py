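"""Synthetic multi-location, two-condition community generator.

Emulates the processed genus tables the analysis consumes: nine cave
locations, two paired conditions (control surface vs dark-zone alteration),
six replicate swabs each, with fixed sequencing depths per domain and
community structure controlled by planted parameters.

Generative model, per domain and location:

* control communities are compositional: genus weights are
  ``10^(baseline + location effect)`` with the baseline spread and the
  per-genus location heterogeneity both on the log10 scale; proportions are
  the normalized weights.
* dark-zone communities apply planted condition effects directly on the
  proportion scale: an effect genus with target Δlog10 ``e`` gets its
  control proportion multiplied by ``10^e``; dark-zone-specific genera
  (hard zeros in every control) get a fixed target proportion; the
  remaining genera share the leftover mass proportionally.  Planted Δlog
  values are therefore realized exactly in expectation at the reference
  location, making parameter recovery a first-class test.
* counts are multinomial at the configured depth (the post-rarefaction
  scale); a depth-inflation flag emits deeper samples so the rarefaction
  step is exercised for real.  The archaeal table keeps its own small,
  deterministic per-condition totals (dark zones strongly depleted) and is
  never rarefied downstream.
* qPCR copies/ng are log-normal around per-condition means.

All randomness flows from one master seed through named substreams (per
domain, per sample), so regenerating a subset of samples is stable.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables_io import (
    DEFAULT_LOCATIONS,
    AbundanceTable,
    QPCRTable,
    SampleMeta,
)

__all__ = [
    "SyntheticConfig",
    "ScenarioData",
    "generate",
    "make_reference_scenario",
    "with_comparison_location",
]

# planted mass caps for a dark-zone community: no single effect genus may
# exceed _MAX_GENUS_MASS, and the summed effect mass is rescaled down to fit
# the _MAX_PLANTED_MASS budget left after the fixed dz-specific proportions;
# realized (post-cap) effects are recorded in the truth
_MAX_PLANTED_MASS = 0.85
_MAX_GENUS_MASS = 0.3


def _rng(seed: int, *names: str) -> np.random.Generator:
    keys = [zlib.crc32(n.encode("utf-8")) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *keys]))


@dataclass
class SyntheticConfig:
    """Generative parameters; defaults follow the nine-location paired design
    with 6 replicates per condition and the study sequencing depths."""

    locations: tuple[str, ...] = DEFAULT_LOCATIONS
    reference_location: str = "Apse"
    n_replicates: int = 6
    depths: dict[str, int] = field(
        default_factory=lambda: {"bacteria": 13467, "fungi": 12753, "archaea": 500}
    )
    n_genera: dict[str, int] = field(
        default_factory=lambda: {"bacteria": 150, "fungi": 40, "archaea": 7}
    )
    baseline_logabund_sd: float = 1.0
    baseline_clip: float = 2.0
    location_effect_sd: float = 0.3
    #: domain -> genus -> target Δlog10 at the reference location
    dz_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    #: per-location spread of condition effects away from the reference
    dz_effect_perturb_sd: float = 0.0
    #: effect genera whose effect exists only at the reference location
    reference_only: dict[str, tuple[str, ...]] = field(default_factory=dict)
    #: domain -> genus -> fixed control log10 weight (overrides the baseline draw)
    control_logweights: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_cosmopolitan: dict[str, tuple[str, ...]] = field(default_factory=dict)
    planted_dz_specific_all: dict[str, tuple[str, ...]] = field(default_factory=dict)
    #: domain -> genus -> tuple of member locations
    planted_dz_specific_subset: dict[str, dict[str, tuple[str, ...]]] = field(
        default_factory=dict
    )
    cosmopolitan_logweight: tuple[float, float] = (1.8, 2.2)
    dz_specific_proportion: float = 0.004
    #: log10 spread of dz-specific genus abundance across locations
    dz_specific_logabund_sd: float = 0.0
    archaea_dz_reads_dlog: float = -1.0
    archaea_dlog_perturb_sd: float = 0.0
    qpcr_base: dict[str, float] = field(
        default_factory=lambda: {"bacteria": 1e5, "archaea": 1e4, "fungi": 5e4}
    )
    qpcr_dz_dlog: dict[str, float] = field(
        default_factory=lambda: {"bacteria": 0.8, "archaea": -2.8, "fungi": 1.0}
    )
    qpcr_dlog_perturb_sd: float = 0.0
    qpcr_log_sd: float = 0.15
    depth_inflation: float = 0.0
    seed: int = 0


@dataclass(eq=False)
class ScenarioData:
    """One generated dataset plus the ground truth that produced it."""

    tables: dict[str, AbundanceTable]
    qpcr: QPCRTable
    samples: tuple[SampleMeta, ...]
    truth: dict
    config: SyntheticConfig


def _genus_pool(domain: str, n: int) -> list[str]:
    return [f"{domain[:3]}_g{i:03d}" for i in range(n)]


def _validate_config(config: SyntheticConfig) -> dict[str, list[str]]:
    for name in (
        "baseline_logabund_sd",
        "location_effect_sd",
        "dz_effect_perturb_sd",
        "archaea_dlog_perturb_sd",
        "qpcr_dlog_perturb_sd",
        "qpcr_log_sd",
    ):
        if getattr(config, name) < 0:
            raise ValueError(f"{name} must be >= 0")
    if config.n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if config.reference_location not in config.locations:
        raise ValueError(
            f"reference_location {config.reference_location!r} not in locations"
        )
    if not (0 < config.dz_specific_proportion < 0.5):
        raise ValueError("dz_specific_proportion must be in (0, 0.5)")
    pools = {}
    for domain, n in config.n_genera.items():
        if int(config.depths.get(domain, 0)) < 1:
            raise ValueError(f"depth for {domain!r} must be >= 1")
        pool = _genus_pool(domain, int(n))
        pool_set = set(pool)
        planted_sets = {
            "cosmopolitan": set(config.planted_cosmopolitan.get(domain, ())),
            "dz_specific_all": set(
                config.planted_dz_specific_all.get(domain, ())
            ),
            "dz_specific_subset": set(
                config.planted_dz_specific_subset.get(domain, {})
            ),
        }
        effects = set(config.dz_effects.get(domain, {}))
        refonly = set(config.reference_only.get(domain, ()))
        weights = set(config.control_logweights.get(domain, {}))
        for label, s in {
            **planted_sets,
            "dz_effects": effects,
            "reference_only": refonly,
            "control_logweights": weights,
        }.items():
            unknown = s - pool_set
            if unknown:
                raise ValueError(
                    f"planted genus not in genus pool ({domain}/{label}): "
                    f"{sorted(unknown)}"
                )
        specific = planted_sets["dz_specific_all"] | planted_sets[
            "dz_specific_subset"
        ]
        if planted_sets["dz_specific_all"] & planted_sets["dz_specific_subset"]:
            raise ValueError(f"overlapping dz_specific sets in {domain}")
        if planted_sets["cosmopolitan"] & specific:
            raise ValueError(
                f"cosmopolitan and dz_specific sets overlap in {domain}"
            )
        if effects & specific:
            raise ValueError(
                f"dz_effects and dz_specific sets overlap in {domain}"
            )
        if refonly - effects:
            raise ValueError(
                f"reference_only genera must carry dz_effects in {domain}"
            )
        for genus, locs in config.planted_dz_specific_subset.get(
            domain, {}
        ).items():
            bad = set(locs) - set(config.locations)
            if bad:
                raise ValueError(
                    f"unknown location(s) {sorted(bad)} for subset genus "
                    f"{genus!r}"
                )
            if not locs or set(locs) == set(config.locations):
                raise ValueError(
                    f"subset genus {genus!r} must name a proper non-empty "
                    "location subset"
                )
        pools[domain] = pool
    return pools


def _make_samples(config: SyntheticConfig) -> tuple[SampleMeta, ...]:
    samples = []
    for loc in config.locations:
        tag = loc.replace(" ", "_")
        for cond, letter in (("control", "C"), ("dark_zone", "D")):
            for rep in range(1, config.n_replicates + 1):
                samples.append(
                    SampleMeta(
                        sample_id=f"{tag}.{letter}{rep}",
                        location=loc,
                        condition=cond,
                        replicate=rep,
                    )
                )
    return tuple(samples)


def _domain_proportions(
    config: SyntheticConfig, domain: str, pool: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Expected control and dark-zone proportions (genus x location)."""
    n = len(pool)
    locs = list(config.locations)
    ref = config.reference_location
    idx = {g: i for i, g in enumerate(pool)}

    base = _rng(config.seed, "baseline", domain).normal(
        0.0, config.baseline_logabund_sd, n
    )
    np.clip(base, -config.baseline_clip, config.baseline_clip, out=base)
    cosmo = list(config.planted_cosmopolitan.get(domain, ()))
    if cosmo:
        lo, hi = config.cosmopolitan_logweight
        draws = _rng(config.seed, "cosmo", domain).uniform(lo, hi, len(cosmo))
        for g, w in zip(cosmo, draws):
            base[idx[g]] = w
    for g, w in config.control_logweights.get(domain, {}).items():
        base[idx[g]] = float(w)

    loc_eff = _rng(config.seed, "loc", domain).normal(
        0.0, config.location_effect_sd, (n, len(locs))
    )

    specific_all = list(config.planted_dz_specific_all.get(domain, ()))
    specific_subset = config.planted_dz_specific_subset.get(domain, {})
    specific = set(specific_all) | set(specific_subset)
    effects = config.dz_effects.get(domain, {})
    refonly = set(config.reference_only.get(domain, ()))

    weights = np.power(10.0, base[:, None] + loc_eff)
    for g in specific:
        weights[idx[g], :] = 0.0  # hard zeros on every control surface
    p = weights / weights.sum(axis=0)

    perturb_rng = _rng(config.seed, "perturb", domain)
    perturb = perturb_rng.normal(
        0.0, config.dz_effect_perturb_sd, (len(effects), len(locs))
    )
    spec_list = sorted(specific)
    spec_wobble = _rng(config.seed, "spec_abund", domain).normal(
        0.0, config.dz_specific_logabund_sd, (len(spec_list), len(locs))
    )
    spec_prop = {
        (g, loc): config.dz_specific_proportion * 10.0 ** spec_wobble[i, j]
        for i, g in enumerate(spec_list)
        for j, loc in enumerate(locs)
    }

    q = np.zeros_like(p)
    realized: dict[str, dict[str, float | None]] = {
        g: {} for g in effects
    }
    null_shift: dict[str, float] = {}
    effect_list = list(effects)
    for j, loc in enumerate(locs):
        q_raw = np.zeros(n)
        active = []
        for k, g in enumerate(effect_list):
            if loc != ref and g in refonly:
                realized[g][loc] = None  # effect exists at the reference only
                continue
            e = effects[g] if loc == ref else effects[g] + perturb[k, j]
            q_raw[idx[g]] = min(p[idx[g], j] * 10.0 ** e, _MAX_GENUS_MASS)
            active.append(g)
        spec_mass = 0.0
        for g in specific_all:
            q_raw[idx[g]] = spec_prop[(g, loc)]
            spec_mass += spec_prop[(g, loc)]
        for g, member_locs in specific_subset.items():
            if loc in member_locs:
                q_raw[idx[g]] = spec_prop[(g, loc)]
                spec_mass += spec_prop[(g, loc)]
        eff_rows = [idx[g] for g in active]
        eff_mass = q_raw[eff_rows].sum()
        budget = _MAX_PLANTED_MASS - spec_mass
        if budget <= 0:
            raise ValueError(
                "dz_specific proportions exceed the planted mass budget"
            )
        if eff_mass > budget:
            q_raw[eff_rows] *= budget / eff_mass
        mass = q_raw.sum()
        planted_rows = eff_rows + [idx[g] for g in specific]
        null_mask = np.ones(n, dtype=bool)
        null_mask[planted_rows] = False
        p_null = p[null_mask, j].sum()
        if p_null <= 0:
            raise ValueError(
                f"no probability mass left for non-effect genera at {loc!r}"
            )
        c = (1.0 - mass) / p_null
        q_col = q_raw.copy()
        q_col[null_mask] = c * p[null_mask, j]
        q[:, j] = q_col / q_col.sum()
        null_shift[loc] = float(np.log10(c))
        for g in active:
            i = idx[g]
            realized[g][loc] = float(np.log10(q[i, j] / p[i, j]))

    p_df = pd.DataFrame(p, index=pool, columns=locs)
    q_df = pd.DataFrame(q, index=pool, columns=locs)
    truth = {"dz_effects_realized": realized, "null_shift": null_shift}
    return p_df, q_df, truth


def generate(config: SyntheticConfig) -> ScenarioData:
    """Generate per-domain abundance tables, a qPCR table and the truth record."""
    pools = _validate_config(config)
    samples = _make_samples(config)
    ref = config.reference_location

    # archaeal per-location dark-zone totals (deterministic per seed)
    arch_rng = _rng(config.seed, "arch_depth")
    arch_dz_depths = {}
    for loc in config.locations:
        shift = 0.0 if loc == ref else float(
            arch_rng.normal(0.0, config.archaea_dlog_perturb_sd)
        )
        arch_dz_depths[loc] = max(
            1,
            int(
                round(
                    config.depths["archaea"]
                    * 10.0 ** (config.archaea_dz_reads_dlog + shift)
                )
            ),
        )

    tables: dict[str, AbundanceTable] = {}
    truth: dict = {
        "seed": config.seed,
        "dz_effects_planted": {
            d: dict(v) for d, v in config.dz_effects.items()
        },
        "dz_effects_realized": {},
        "null_shift": {},
        "reference_expected_proportions": {},
        "categories": {
            "cosmopolitan": {
                d: sorted(v) for d, v in config.planted_cosmopolitan.items()
            },
            "dz_specific_all": {
                d: sorted(v)
                for d, v in config.planted_dz_specific_all.items()
            },
            "dz_specific_subset": {
                d: {g: sorted(locs) for g, locs in v.items()}
                for d, v in config.planted_dz_specific_subset.items()
            },
        },
        "archaea_dz_depths": arch_dz_depths,
        "qpcr_dlog_realized": {},
    }

    for domain, pool in pools.items():
        p_df, q_df, dom_truth = _domain_proportions(config, domain, pool)
        truth["dz_effects_realized"][domain] = dom_truth["dz_effects_realized"]
        truth["null_shift"][domain] = dom_truth["null_shift"]
        truth["reference_expected_proportions"][domain] = {
            "control": {g: float(p_df.loc[g, ref]) for g in pool},
            "dark_zone": {g: float(q_df.loc[g, ref]) for g in pool},
        }
        if domain == "archaea":
            control_depth = int(config.depths[domain])
            depth_of = lambda s: (
                control_depth
                if s.condition == "control"
                else arch_dz_depths[s.location]
            )
        else:
            depth = int(
                round(config.depths[domain] * (1.0 + config.depth_inflation))
            )
            depth_of = lambda s: depth
        cols = {}
        for s in samples:
            probs = (
                p_df[s.location] if s.condition == "control" else q_df[s.location]
            ).to_numpy()
            probs = probs / probs.sum()
            rng = _rng(config.seed, "counts", domain, s.sample_id)
            cols[s.sample_id] = rng.multinomial(depth_of(s), probs)
        counts = pd.DataFrame(cols, index=pool, dtype=np.int64)
        counts.index.name = "genus"
        tables[domain] = AbundanceTable(
            domain=domain, counts=counts, samples=samples
        )

    # qPCR: log-normal copies/ng around per-condition means
    qpcr_rows = []
    for domain in pools:
        loc_rng = _rng(config.seed, "qpcr_loc", domain)
        dlog_by_loc = {}
        for loc in config.locations:
            shift = 0.0 if loc == ref else float(
                loc_rng.normal(0.0, config.qpcr_dlog_perturb_sd)
            )
            dlog_by_loc[loc] = config.qpcr_dz_dlog[domain] + shift
        truth["qpcr_dlog_realized"][domain] = dict(dlog_by_loc)
        for s in samples:
            mu = np.log10(config.qpcr_base[domain])
            if s.condition == "dark_zone":
                mu += dlog_by_loc[s.location]
            noise = float(
                _rng(config.seed, "qpcr", domain, s.sample_id).normal(
                    0.0, config.qpcr_log_sd
                )
            )
            qpcr_rows.append(
                {
                    "sample_id": s.sample_id,
                    "domain": domain,
                    "copies_per_ng": float(10.0 ** (mu + noise)),
                }
            )
    qpcr = QPCRTable(data=pd.DataFrame(qpcr_rows))
    return ScenarioData(
        tables=tables, qpcr=qpcr, samples=samples, truth=truth, config=config
    )


def _scenario_config(seed: int) -> SyntheticConfig:
    """The reference-scenario design: 27 bacterial + 14 fungal effect genera
    (|Δlog| > 1 at the reference), planted biogeography categories, and
    per-location perturbations wide enough that downstream percent
    similarities spread well below 100%."""
    bac = _genus_pool("bacteria", 150)
    fun = _genus_pool("fungi", 40)

    bac_effects: dict[str, float] = {}
    bac_weights: dict[str, float] = {}
    # anchors: abundant enough for tight parameter recovery on both sides
    for g, w, e in (
        (bac[0], 2.6, -1.2),
        (bac[1], 2.5, -1.3),
        (bac[2], 1.2, 1.3),
        (bac[3], 1.1, 1.25),
    ):
        bac_weights[g], bac_effects[g] = w, e
    # reference-only effects (null at every other location)
    for g, w, e in (
        (bac[4], 0.6, 1.5),
        (bac[5], 1.1, -1.7),
        (bac[6], 0.4, 1.7),
    ):
        bac_weights[g], bac_effects[g] = w, e
    # minor effect genera: counter-selected genera are abundant enough that
    # their depth of counter-selection stays resolvable (not just
    # present/absent), positive effects stay light so the planted mass
    # never saturates the reference dark-zone community
    for i in range(20):
        g = bac[7 + i]
        if i % 2 == 0:
            bac_weights[g] = 1.5 + 0.05 * i
            bac_effects[g] = -(2.0 + 0.07 * i)
        else:
            bac_weights[g] = 0.15 + 0.015 * i
            bac_effects[g] = 1.25 + 0.012 * i

    fun_effects: dict[str, float] = {}
    fun_weights: dict[str, float] = {}
    for g, w, e in (
        (fun[0], 2.0, -1.3),
        (fun[1], 1.9, -1.2),
        (fun[2], 0.9, 1.25),
    ):
        fun_weights[g], fun_effects[g] = w, e
    for g, w, e in ((fun[3], 0.3, 1.4), (fun[4], 0.9, -1.6)):
        fun_weights[g], fun_effects[g] = w, e
    for i in range(9):
        g = fun[5 + i]
        if i % 2 == 0:
            fun_weights[g] = 1.4 + 0.06 * i
            fun_effects[g] = -(2.0 + 0.08 * i)
        else:
            fun_weights[g] = 0.2 + 0.03 * i
            fun_effects[g] = 1.25 + 0.03 * i

    return SyntheticConfig(
        dz_effects={"bacteria": bac_effects, "fungi": fun_effects},
        reference_only={
            "bacteria": (bac[4], bac[5], bac[6]),
            "fungi": (fun[3], fun[4]),
        },
        control_logweights={"bacteria": bac_weights, "fungi": fun_weights},
        planted_cosmopolitan={
            "bacteria": tuple(bac[30:38]),
            "fungi": tuple(fun[15:19]),
        },
        planted_dz_specific_all={"bacteria": tuple(bac[40:46])},
        planted_dz_specific_subset={
            "bacteria": {
                bac[46]: ("Nave high",),
                bac[47]: ("Bulls left",),
                bac[48]: ("Bulls center",),
            },
            "fungi": {
                fun[19]: ("Apse",),
                fun[20]: ("Apse",),
                fun[21]: ("Nave high",),
            },
        },
        dz_effect_perturb_sd=2.2,
        dz_specific_proportion=0.005,
        dz_specific_logabund_sd=0.2,
        location_effect_sd=0.3,
        archaea_dlog_perturb_sd=0.4,
        qpcr_dlog_perturb_sd=0.6,
        qpcr_log_sd=0.15,
        depth_inflation=0.1,
        seed=int(seed),
    )


def make_reference_scenario(seed: int) -> ScenarioData:
    """Convenience preset approximating the study setting (deterministic per seed)."""
    return generate(_scenario_config(seed))


def with_comparison_location(
    tables: Mapping[str, AbundanceTable],
    qpcr: QPCRTable,
    samples: Sequence[SampleMeta],
    source_location: str,
    new_location: str,
    flip_conditions: bool = False,
) -> tuple[dict[str, AbundanceTable], QPCRTable, tuple[SampleMeta, ...]]:
    """Append a constructed location that copies one location's data.

    With ``flip_conditions`` the control and dark-zone labels are swapped in
    the copy, planting a location whose variation has the opposite sign for
    every criterion.  Used for clone-of-reference and sign-flip checks.
    """
    if new_location in {s.location for s in samples}:
        raise ValueError(f"location {new_location!r} already exists")
    tag = new_location.replace(" ", "_")

    def _transform(meta: SampleMeta) -> SampleMeta:
        cond = meta.condition
        if flip_conditions:
            cond = "dark_zone" if cond == "control" else "control"
        return SampleMeta(
            sample_id=f"{tag}__{meta.sample_id}",
            location=new_location,
            condition=cond,
            replicate=meta.replicate,
        )

    new_tables: dict[str, AbundanceTable] = {}
    for domain, table in tables.items():
        src_ids = table.select_ids(location=source_location)
        if not src_ids:
            raise ValueError(
                f"no samples at {source_location!r} in the {domain} table"
            )
        extra_meta = tuple(_transform(table.meta(sid)) for sid in src_ids)
        extra = table.counts[src_ids].copy()
        extra.columns = [m.sample_id for m in extra_meta]
        counts = pd.concat([table.counts, extra], axis=1)
        new_tables[domain] = AbundanceTable(
            domain=domain, counts=counts, samples=table.samples + extra_meta
        )

    src_meta = [s for s in samples if s.location == source_location]
    new_samples = tuple(samples) + tuple(_transform(s) for s in src_meta)
    extra_rows = []
    for s in src_meta:
        rows = qpcr.data[qpcr.data["sample_id"] == s.sample_id]
        for _, row in rows.iterrows():
            extra_rows.append(
                {
                    "sample_id": _transform(s).sample_id,
                    "domain": row["domain"],
                    "copies_per_ng": row["copies_per_ng"],
                }
            )
    new_qpcr = QPCRTable(
        data=pd.concat(
            [qpcr.data, pd.DataFrame(extra_rows)], ignore_index=True
        )
    )
    return new_tables, new_qpcr, new_samples
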