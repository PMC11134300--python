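"""Synthetic enclosure populations with known transmission structure.

Generates the three raw inputs of the pipeline — a pedigree, an RFID
event log, and per-gut-section ASV count tables — for a two-subspecies
house-mouse population bred in demes inside enclosures.  The generative
model mixes three transmission channels into each individual's latent
log-composition: a vertical channel from the parents whose weight follows a
hump-shaped function of offspring age (zero before weaning, peaking in
young adulthood, decaying thereafter), a social channel averaging contact
partners' compositions weighted by co-occupancy time, and a shared
environmental pool.  Because the mixing weights are known, downstream
estimates can be validated against planted truth.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._rng import substream
from .community_matrix import CountTable, SampleMeta
from .pedigree_kinship import PedigreeTable
from .rfid_social import (
    ContactMatrix,
    EventRecord,
    Visit,
    contact_matrix,
    parse_visits,
    write_events_csv,
)

__all__ = [
    "AgeProfile",
    "SimConfig",
    "SimTruth",
    "simulate_pedigree",
    "simulate_visits",
    "simulate_event_log",
    "simulate_counts",
    "simulate_dataset",
    "SimDataset",
]

SECTIONS = ("ileum", "cecum", "colon")


@dataclass
class AgeProfile:
    """Shape of the vertical-transmission weight over offspring age.

    Zero before ``weaning_age`` (pre-weaning gut communities are shaped by
    milk, not by shared food and coprophagy), rising linearly to the full
    vertical weight at ``peak_age`` (around dispersal from the parental
    territory), then decaying exponentially at ``decay_rate`` per day.
    """

    weaning_age: float = 23.0
    peak_age: float = 65.0
    decay_rate: float = 0.04

    def weight(self, age_days: float, w_vertical: float) -> float:
        if age_days <= self.weaning_age:
            return 0.0
        if age_days <= self.peak_age:
            return w_vertical * (age_days - self.weaning_age) / (
                self.peak_age - self.weaning_age
            )
        return w_vertical * float(np.exp(-self.decay_rate * (age_days - self.peak_age)))


@dataclass
class SimConfig:
    n_founders_per_subspecies: int = 12
    n_demes: int = 3
    p_within_deme_mating: float = 0.9
    experiment_length: int = 270
    litter_size_mean: float = 6.0
    n_asv: int = 200
    depth_range: tuple[int, int] = (2000, 10000)
    w_vertical: float = 1.0
    w_social: float = 1.0
    w_env: float = 1.0
    sigma_individual: float = 0.4
    age_profile: AgeProfile = field(default_factory=AgeProfile)
    seed: int = 0
    # population / breeding details
    subspecies: tuple[str, ...] = ("MMM", "MMD")
    max_individuals_per_subspecies: int = 60
    max_generations: int | None = None
    gestation_days: int = 19
    maturity_age_days: int = 40
    litter_interval_days: int = 30
    p_litter_per_cycle: float = 0.5
    founder_age_at_release: int = 60
    # movement / RFID details
    n_nestboxes_per_subspecies: int = 6
    deme_preference: float = 0.8
    visits_per_mouse: int = 60
    visit_duration_mean_s: float = 600.0
    drop_fraction: float = 0.0
    # community details
    n_mixing_rounds: int = 3
    env_log_sd: float = 1.5
    ileum_keep_fraction: float = 0.05
    ileum_background: float = 0.01
    sections: tuple[str, ...] = SECTIONS

    def __post_init__(self) -> None:
        if self.w_vertical + self.w_social + self.w_env <= 0:
            raise ValueError("transmission weights must sum to a positive value")
        if min(self.w_vertical, self.w_social, self.w_env) < 0:
            raise ValueError("transmission weights must be non-negative")
        if not 0.0 <= self.p_within_deme_mating <= 1.0:
            raise ValueError("p_within_deme_mating must be a probability")
        if self.depth_range[0] < 1 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("depth_range must satisfy 1 <= min <= max")
        if not 0.0 <= self.drop_fraction < 1.0:
            raise ValueError("drop_fraction must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "age_profile" in raw:
            raw["age_profile"] = AgeProfile(**raw["age_profile"])
        for key in ("depth_range", "subspecies", "sections"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["age_profile"] = dataclasses.asdict(self.age_profile)
        for key in ("depth_range", "subspecies", "sections"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class SimTruth:
    """Planted ground truth accompanying a simulated data set."""

    pedigree: PedigreeTable
    contacts: ContactMatrix
    latent_compositions: pd.DataFrame = field(repr=False)
    weights: dict = field(default_factory=dict)
    env_log_abundance: np.ndarray | None = field(default=None, repr=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "weights": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                        for k, v in self.weights.items()},
            "individuals": list(self.latent_compositions.index),
            "env_log_abundance": (self.env_log_abundance.tolist()
                                  if self.env_log_abundance is not None else None),
        }
        Path(path).write_text(json.dumps(payload) + "\n")


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(config: SimConfig) -> PedigreeTable:
    """Breed a demic two-subspecies population from released founders.

    Founders (unknown parents, released as adults) are assigned to demes
    round-robin.  Each breeding cycle, mature females litter with a fixed
    probability; the sire is drawn from the female's deme with probability
    ``p_within_deme_mating`` and uniformly from all same-subspecies males
    otherwise.  Litter sizes are Poisson; there are no cross-subspecies
    matings.  ``max_generations = 0`` suppresses breeding entirely.
    """
    rng = substream(config.seed, "pedigree")
    rows = []
    counters = {s: 0 for s in config.subspecies}

    def new_id(subsp: str) -> str:
        counters[subsp] += 1
        return f"{subsp}_{counters[subsp]:03d}"

    for subsp in config.subspecies:
        for k in range(config.n_founders_per_subspecies):
            rows.append({
                "id": new_id(subsp), "dam": None, "sire": None,
                "sex": "F" if k % 2 == 0 else "M", "subspecies": subsp,
                "deme": f"{subsp}_d{k % config.n_demes}",
                "birth_day": -config.founder_age_at_release,
                "generation": 0,
            })

    breeding = config.max_generations is None or config.max_generations > 0
    if breeding:
        for subsp in config.subspecies:
            sexes = {r["sex"] for r in rows if r["subspecies"] == subsp}
            if sexes != {"F", "M"}:
                raise ValueError(f"cannot breed: subspecies {subsp} lacks founders of both sexes")

    pop_count = {s: config.n_founders_per_subspecies for s in config.subspecies}
    if breeding:
        for day in range(0, config.experiment_length, config.litter_interval_days):
            conception = day - config.gestation_days
            for subsp in config.subspecies:
                if pop_count[subsp] >= config.max_individuals_per_subspecies:
                    continue
                pop = [r for r in rows if r["subspecies"] == subsp]
                mature = [r for r in pop
                          if conception - r["birth_day"] >= config.maturity_age_days]
                females = [r for r in mature if r["sex"] == "F"]
                males = [r for r in mature if r["sex"] == "M"]
                if not females or not males:
                    continue
                for dam in females:
                    if rng.random() >= config.p_litter_per_cycle:
                        continue
                    deme_males = [m for m in males if m["deme"] == dam["deme"]]
                    if deme_males and rng.random() < config.p_within_deme_mating:
                        sire = deme_males[int(rng.integers(len(deme_males)))]
                    else:
                        sire = males[int(rng.integers(len(males)))]
                    gen = max(dam["generation"], sire["generation"]) + 1
                    if config.max_generations is not None and gen > config.max_generations:
                        continue
                    n_pups = int(rng.poisson(config.litter_size_mean))
                    # spread birth dates across the cycle so sampling ages vary
                    born = min(day + int(rng.integers(config.litter_interval_days)),
                               config.experiment_length - 1)
                    for _ in range(n_pups):
                        if pop_count[subsp] >= config.max_individuals_per_subspecies:
                            break
                        pop_count[subsp] += 1
                        rows.append({
                            "id": new_id(subsp), "dam": dam["id"], "sire": sire["id"],
                            "sex": "F" if rng.random() < 0.5 else "M",
                            "subspecies": subsp, "deme": dam["deme"],
                            "birth_day": born, "generation": gen,
                        })
    return PedigreeTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# RFID movement
# ---------------------------------------------------------------------------

def simulate_visits(pedigree: PedigreeTable, config: SimConfig) -> list[Visit]:
    """Draw non-overlapping nest-box visit bouts for every mouse.

    Each mouse prefers its own deme's boxes with probability
    ``deme_preference`` and otherwise roams its subspecies' enclosure.
    Visits start after weaning age and never overlap within a mouse (a
    mouse cannot be in two boxes at once).
    """
    rng = substream(config.seed, "visits")
    day_s = 86_400.0
    horizon = config.experiment_length * day_s
    boxes: dict[str, list[str]] = {}
    box_deme: dict[str, str] = {}
    for subsp in config.subspecies:
        boxes[subsp] = []
        for b in range(config.n_nestboxes_per_subspecies):
            box = f"{subsp}_box{b}"
            boxes[subsp].append(box)
            box_deme[box] = f"{subsp}_d{b % config.n_demes}"
    visits: list[Visit] = []
    for r in pedigree.table.itertuples(index=False):
        active_from = max(0.0, (r.birth_day + config.age_profile.weaning_age) * day_s)
        if active_from >= horizon:
            continue
        n = rng.poisson(config.visits_per_mouse)
        if n == 0:
            continue
        starts = np.sort(rng.uniform(active_from, horizon, n))
        durations = np.maximum(rng.exponential(config.visit_duration_mean_s, n), 10.0)
        own = [b for b in boxes[r.subspecies] if box_deme[b] == r.deme]
        cursor = active_from
        for s, d in zip(starts, durations):
            s = max(s, cursor + 5.0)
            e = min(s + d, horizon)
            if e - s < 10.0:
                continue
            if own and rng.random() < config.deme_preference:
                box = own[int(rng.integers(len(own)))]
            else:
                box = boxes[r.subspecies][int(rng.integers(len(boxes[r.subspecies])))]
            visits.append(Visit(r.id, box, s, e))
            cursor = e
    visits.sort(key=lambda v: (v.start, v.mouse_id))
    return visits


def simulate_event_log(
    pedigree: PedigreeTable, config: SimConfig, visits: list[Visit] | None = None
) -> list[EventRecord]:
    """Emit the four-read dual-antenna pattern for every simulated visit.

    Entry is outer-then-inner, exit inner-then-outer, with the inner reads
    at the visit's start and end.  A configurable fraction of reads is
    dropped to exercise parser resynchronisation.
    """
    if visits is None:
        visits = simulate_visits(pedigree, config)
    rng = substream(config.seed, "event_dropout")
    events: list[EventRecord] = []
    for v in visits:
        quad = [
            EventRecord(v.start - 2.0, v.mouse_id, v.nestbox_id, "outer"),
            EventRecord(v.start, v.mouse_id, v.nestbox_id, "inner"),
            EventRecord(v.end, v.mouse_id, v.nestbox_id, "inner"),
            EventRecord(v.end + 2.0, v.mouse_id, v.nestbox_id, "outer"),
        ]
        for e in quad:
            if config.drop_fraction > 0 and rng.random() < config.drop_fraction:
                continue
            events.append(e)
    events.sort(key=lambda e: (e.timestamp, e.mouse_id, e.reader))
    return events


# ---------------------------------------------------------------------------
# ASV counts
# ---------------------------------------------------------------------------

def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max()
    e = np.exp(z)
    return e / e.sum()


def simulate_counts(
    pedigree: PedigreeTable,
    contacts: ContactMatrix,
    config: SimConfig,
    w_social_asv: np.ndarray | None = None,
    w_vertical_asv: np.ndarray | None = None,
) -> tuple[CountTable, SampleMeta, SimTruth]:
    """Generate per-section ASV count tables from the transmission model.

    Every individual's latent log-composition is a weighted mix of its
    parents' mean (weight following the age profile), the contact-weighted
    mean of its partners, and the environmental pool, divided by the total
    active weight, plus individual log-scale noise.  Mixing is iterated
    ``n_mixing_rounds`` times in birth order so influence propagates along
    the network.  Per-section sparsification masks reproduce the ileum's
    low diversity; counts are multinomial at a uniform random depth.
    Optional per-ASV weight vectors override the scalar social/vertical
    weights (used to plant ASV-level transmission signals).
    """
    rng = substream(config.seed, "counts")
    ids = pedigree.ids
    idx = {m: i for i, m in enumerate(ids)}
    cidx = {m: i for i, m in enumerate(contacts.individuals)}
    missing = [m for m in ids if m not in cidx]
    if missing:
        raise ValueError(f"contact matrix missing individuals: {missing[:5]}")
    C = contacts.values  # validated symmetric by ContactMatrix
    n_asv = config.n_asv
    lam_env = rng.normal(0.0, config.env_log_sd, n_asv)
    eps = rng.normal(0.0, config.sigma_individual, (len(ids), n_asv))

    ws = np.full(n_asv, config.w_social) if w_social_asv is None \
        else np.asarray(w_social_asv, dtype=float)
    wv_full = np.full(n_asv, config.w_vertical) if w_vertical_asv is None \
        else np.asarray(w_vertical_asv, dtype=float)
    we = np.full(n_asv, config.w_env, dtype=float)

    t = pedigree.table.set_index("id")
    order = pedigree.topological_order()
    ages = {m: float(config.experiment_length - t.at[m, "birth_day"]) for m in ids}
    lam = np.tile(lam_env, (len(ids), 1)) + eps

    for _ in range(config.n_mixing_rounds):
        for m in order:
            i = idx[m]
            dam, sire = t.at[m, "dam"], t.at[m, "sire"]
            has_parents = dam is not None and sire is not None
            if has_parents:
                parent_mean = 0.5 * (lam[idx[dam]] + lam[idx[sire]])
                age_scale = (config.age_profile.weight(ages[m], 1.0)
                             if config.w_vertical > 0 or w_vertical_asv is not None
                             else 0.0)
                wv = wv_full * age_scale
            else:
                parent_mean = lam_env
                wv = np.zeros(n_asv)
            crow = C[cidx[m]].copy()
            crow[cidx[m]] = 0.0
            # restrict to simulated individuals in contact-matrix order
            weights = np.array([crow[cidx[o]] for o in ids])
            weights[i] = 0.0
            if weights.sum() > 0:
                social_mean = (weights[:, None] * lam).sum(axis=0) / weights.sum()
                ws_eff = ws
            else:
                social_mean = lam_env
                ws_eff = np.zeros(n_asv)
            total = wv + ws_eff + we
            total = np.where(total > 0, total, 1.0)
            # individual noise enters through the environmental-acquisition
            # channel, so strongly transmitted ASVs track their source
            lam[i] = (wv * parent_mean + ws_eff * social_mean
                      + we * (lam_env + eps[i])) / total

    comps = np.array([_softmax(row) for row in lam])
    asv_ids = [f"ASV{k + 1:04d}" for k in range(n_asv)]

    masks = {}
    k_keep = max(1, int(np.ceil(config.ileum_keep_fraction * n_asv)))
    dominant = np.argsort(lam_env)[::-1][:k_keep]
    ileum_mask = np.full(n_asv, config.ileum_background)
    ileum_mask[dominant] = 1.0
    for sec in config.sections:
        masks[sec] = ileum_mask if sec == "ileum" else np.ones(n_asv)

    count_rows, meta_rows, sample_ids = [], [], []
    for m in ids:
        i = idx[m]
        for sec in config.sections:
            p = comps[i] * masks[sec]
            p = p / p.sum()
            depth = int(rng.integers(config.depth_range[0], config.depth_range[1] + 1))
            count_rows.append(rng.multinomial(depth, p))
            sample_ids.append(f"{m}:{sec}")
            meta_rows.append({
                "sample_id": f"{m}:{sec}", "individual": m, "gut_section": sec,
                "subspecies": t.at[m, "subspecies"], "sex": t.at[m, "sex"],
                "age_days": ages[m],
            })
    counts = CountTable(pd.DataFrame(count_rows, index=sample_ids, columns=asv_ids))
    meta = SampleMeta(pd.DataFrame(meta_rows))
    truth = SimTruth(
        pedigree=pedigree,
        contacts=contacts,
        latent_compositions=pd.DataFrame(comps, index=ids, columns=asv_ids),
        weights={"w_vertical": wv_full if w_vertical_asv is not None else config.w_vertical,
                 "w_social": ws if w_social_asv is not None else config.w_social,
                 "w_env": config.w_env},
        env_log_abundance=lam_env,
    )
    return counts, meta, truth


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

@dataclass
class SimDataset:
    config: SimConfig
    pedigree: PedigreeTable
    visits: list[Visit] = field(repr=False)
    events: list[EventRecord] = field(repr=False)
    contacts: ContactMatrix = field(repr=False)
    counts: CountTable = field(repr=False)
    meta: SampleMeta = field(repr=False)
    truth: SimTruth = field(repr=False)

    def write(self, outdir: str | Path) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "events": str(outdir / "events.csv"),
            "pedigree": str(outdir / "pedigree.csv"),
            "counts": str(outdir / "counts.tsv"),
            "meta": str(outdir / "meta.csv"),
            "truth": str(outdir / "truth.json"),
        }
        write_events_csv(self.events, paths["events"])
        self.pedigree.to_csv(paths["pedigree"])
        self.counts.to_tsv(paths["counts"])
        self.meta.to_csv(paths["meta"])
        self.truth.to_json(paths["truth"])
        return paths


def simulate_dataset(config: SimConfig, **count_kwargs) -> SimDataset:
    """Run the full generator: pedigree → movement → contacts → counts."""
    pedigree = simulate_pedigree(config)
    visits = simulate_visits(pedigree, config)
    events = simulate_event_log(pedigree, config, visits=visits)
    parsed, _ = parse_visits(events)
    contacts = contact_matrix(parsed, pedigree.ids)
    counts, meta, truth = simulate_counts(pedigree, contacts, config, **count_kwargs)
    return SimDataset(config, pedigree, visits, events, contacts, counts, meta, truth)
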