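"""Seeded generator of synthetic gaze episodes with known ground truth.

The original eye-tracking recordings behind the sandwich-making scenario were
never deposited, so this module stands in for them: it lays out labeled
fixation streams episode by episode, following the behavioral archetypes
observed in that task — a dominant choice, a trending choice, two competing
choices, multiple choices, no glance at the intended target at all, and the
three signaling templates (joint-attention initiation, confirmatory request,
goal referencing).

Every episode is built from explicit budgets: a total duration drawn from a
truncated normal whose realized mean/SD match the configured values, a
missing-data share (explicit MISSING fixations), an ingredient-dwell budget
distributed per archetype, and filler glances elsewhere.  The generator
therefore knows, exactly, each episode's intended target, archetype, planted
template spans, and whether the final ingredient glance was forced to match
the request — which is what makes parameter-recovery tests possible.

Deliberate simplifications: the timeline is gap-free (dropout appears as
explicit MISSING fixations, in chunks long enough never to bridge a glance
merge), and non-template archetypes use only ELSEWHERE fillers so that
template-free episodes cannot contain accidental template matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import json

import numpy as np
from scipy import optimize, stats

from .events import (
    BREAD,
    ELSEWHERE,
    MISSING,
    PARTNER,
    Dataset,
    Episode,
    FixationEvent,
    TargetKind,
    TargetLabel,
)
from .io import write_fixation_table

__all__ = [
    "ARCHETYPES",
    "INGREDIENT_POOL",
    "GeneratorConfig",
    "generate_episode",
    "generate_dataset",
    "write_dataset",
]

ARCHETYPES = (
    "DOMINANT",
    "TRENDING",
    "TWO_COMPETING",
    "MULTI_CHOICE",
    "NO_INTENDED_GLANCE",
    "JOINT_ATTENTION",
    "CONFIRMATORY",
    "GOAL_REFERENCE",
)

#: The 23 selectable ingredients of the tabletop layout.
INGREDIENT_POOL = (
    "lettuce1", "pickle1", "tomato2", "turkey", "roast_beef", "bacon2",
    "mustard", "cheddar_cheese", "onions", "pickle2", "ham", "mayo", "egg",
    "salami", "swiss_cheese", "bologna", "bacon1", "peanut_butter",
    "lettuce2", "pickle3", "tomato1", "ketchup", "jelly",
)

# NO_INTENDED_GLANCE weight reflects the ~8% of episodes (23/276) in which
# the requested target was never glanced at; the rest are conventions.
DEFAULT_MIXTURE = {
    "DOMINANT": 0.35,
    "TRENDING": 0.15,
    "TWO_COMPETING": 0.12,
    "MULTI_CHOICE": 0.10,
    "NO_INTENDED_GLANCE": 0.08,
    "JOINT_ATTENTION": 0.08,
    "CONFIRMATORY": 0.07,
    "GOAL_REFERENCE": 0.05,
}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study conditions.

    Defaults mirror the reference task: 23 ingredients, episode durations
    with mean 3802.56 ms and SD 1596.45 ms, and a 0.65 chance that the final
    ingredient glance is the requested target (the attention-baseline rate).
    """

    n_ingredients: int = 23
    n_episodes: int = 276
    seed: int = 0
    episode_duration_mean_ms: float = 3802.56
    episode_duration_sd_ms: float = 1596.45
    episode_duration_min_ms: float = 500.0
    fixation_duration_median_ms: float = 250.0
    fixation_duration_sigma: float = 0.45
    missing_rate: float = 0.10
    missing_rate_jitter: float = 0.35  # relative SD of per-episode rate
    archetype_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIXTURE)
    )
    last_glance_match_rate: float = 0.65
    min_available: int = 9
    dominant_dwell_share: float = 0.8
    glance_gap_ms: int = 200

    def __post_init__(self) -> None:
        if not 0.0 <= self.last_glance_match_rate <= 1.0:
            raise ValueError("last_glance_match_rate must lie in [0, 1]")
        if self.episode_duration_mean_ms <= 0 or self.episode_duration_sd_ms <= 0:
            raise ValueError("duration parameters must be positive")
        unknown = set(self.archetype_mixture) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes in mixture: {sorted(unknown)}")
        total = sum(self.archetype_mixture.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"mixture weights sum to {total}, expected 1")

    def ingredient_pool(self) -> tuple[str, ...]:
        if self.n_ingredients <= len(INGREDIENT_POOL):
            return INGREDIENT_POOL[: self.n_ingredients]
        extra = tuple(
            f"ingredient{k:02d}"
            for k in range(len(INGREDIENT_POOL) + 1, self.n_ingredients + 1)
        )
        return INGREDIENT_POOL + extra


@lru_cache(maxsize=32)
def _truncnorm_params(mean: float, sd: float, lower: float) -> tuple[float, float]:
    """Underlying (mu, sigma) so the lower-truncated normal has (mean, sd)."""

    def moments(x):
        mu, sigma = x
        sigma = abs(sigma)
        a = (lower - mu) / sigma
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.root(moments, x0=[mean, sd])
    if not sol.success:
        raise RuntimeError("truncated-normal moment matching failed to converge")
    mu, sigma = sol.x
    return float(mu), float(abs(sigma))


def _draw_duration(config: GeneratorConfig, rng: np.random.Generator) -> int:
    mu, sigma = _truncnorm_params(
        config.episode_duration_mean_ms,
        config.episode_duration_sd_ms,
        config.episode_duration_min_ms,
    )
    a = (config.episode_duration_min_ms - mu) / sigma
    value = stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, random_state=rng)
    return int(round(float(value)))


def _split_total(
    total: int,
    weights: np.ndarray,
    minimum: int = 1,
) -> list[int]:
    """Largest-remainder split of an integer total along positive weights."""
    n = len(weights)
    if n == 0:
        return []
    if total < n * minimum:
        minimum = max(1, total // n)
    weights = np.asarray(weights, dtype=float)
    raw = weights / weights.sum() * (total - n * minimum)
    base = np.floor(raw).astype(int)
    rem = total - n * minimum - int(base.sum())
    order = np.argsort(-(raw - base), kind="stable")
    for idx in order[:rem]:
        base[idx] += 1
    return [int(b) + minimum for b in base]


@dataclass
class _Seg:
    target: TargetLabel
    dwell: int = 0
    weight: float = 1.0
    template: str | None = None  # pattern name if part of a planted block


def _order_no_adjacent(
    glances: list[TargetLabel],
    final: TargetLabel | None,
    rng: np.random.Generator,
) -> list[TargetLabel]:
    """Shuffle glance targets avoiding same-target adjacency, fixing the last."""
    pool = list(glances)
    tail: list[TargetLabel] = []
    if final is not None:
        pool.remove(final)
        tail = [final]
    ordered: list[TargetLabel] = []
    rng.shuffle(pool)
    prev: TargetLabel | None = None
    while pool:
        choices = [i for i, t in enumerate(pool) if t != prev]
        if not choices:
            choices = list(range(len(pool)))  # stuck; repaired downstream
        i = int(rng.choice(choices))
        prev = pool.pop(i)
        ordered.append(prev)
    return ordered + tail


def _ingredient_glances(
    archetype: str,
    requested: str,
    competitors: list[str],
    match: bool,
    rng: np.random.Generator,
    config: GeneratorConfig,
) -> tuple[list[tuple[TargetLabel, float]], TargetLabel | None]:
    """Per-archetype multiset of (target, dwell-weight) plus forced final."""
    req = TargetLabel.ingredient(requested)

    def comp_targets(k: int) -> list[TargetLabel]:
        picks = rng.choice(len(competitors), size=min(k, len(competitors)),
                           replace=False)
        return [TargetLabel.ingredient(competitors[int(i)]) for i in picks]

    glances: list[tuple[TargetLabel, float]] = []
    if archetype == "DOMINANT":
        share = config.dominant_dwell_share
        k_int = int(rng.integers(2, 5))
        comps = comp_targets(int(rng.integers(1, 4)))
        int_w = rng.lognormal(0.0, 0.3, size=k_int)
        int_w = int_w / int_w.sum() * share
        glances = [(req, float(w)) for w in int_w]
        # competitors also draw repeated glances; what distinguishes the
        # dominant choice is dwell share, not glance count
        comp_counts = [int(rng.integers(1, 3)) for _ in comps]
        comp_w = rng.lognormal(0.0, 0.3, size=sum(comp_counts))
        comp_w = comp_w / comp_w.sum() * (1.0 - share)
        k = 0
        for t, c in zip(comps, comp_counts):
            for _ in range(c):
                glances.append((t, float(comp_w[k])))
                k += 1
    elif archetype == "TRENDING":
        k_int = int(rng.integers(3, 6))
        comps = comp_targets(int(rng.integers(2, 4)))
        share = float(rng.uniform(0.30, 0.45))
        int_w = rng.lognormal(0.0, 0.25, size=k_int)
        int_w = int_w / int_w.sum() * share
        glances = [(req, float(w)) for w in int_w]
        comp_counts = [int(rng.integers(1, max(2, k_int - 1))) for _ in comps]
        comp_n = sum(comp_counts)
        comp_w = rng.lognormal(0.0, 0.25, size=comp_n)
        comp_w = comp_w / comp_w.sum() * (1.0 - share)
        k = 0
        for t, c in zip(comps, comp_counts):
            for _ in range(c):
                glances.append((t, float(comp_w[k])))
                k += 1
    elif archetype == "TWO_COMPETING":
        if not competitors:
            raise ValueError("TWO_COMPETING needs at least 2 available targets")
        comp = comp_targets(1)[0]
        share = float(rng.uniform(0.45, 0.55))
        for w in rng.lognormal(0.0, 0.2, size=2):
            glances.append((req, float(w)))
        for w in rng.lognormal(0.0, 0.2, size=2):
            glances.append((comp, float(w)))
        tot_req = sum(w for t, w in glances if t == req)
        tot_comp = sum(w for t, w in glances if t == comp)
        glances = [
            (t, w / tot_req * share if t == req else w / tot_comp * (1 - share))
            for t, w in glances
        ]
    elif archetype in ("MULTI_CHOICE", "NO_INTENDED_GLANCE"):
        n_targets = int(rng.integers(3, 6))
        if archetype == "MULTI_CHOICE":
            targets = [req] + comp_targets(n_targets - 1)
        else:
            targets = comp_targets(n_targets)
        shares = rng.dirichlet(np.full(len(targets), 5.0))
        for t, s in zip(targets, shares):
            k = int(rng.integers(1, 3))
            sub = rng.dirichlet(np.full(k, 4.0)) * s
            glances += [(t, float(w)) for w in sub]
    else:  # template archetypes share a dominant-lite base
        share = float(rng.uniform(0.5, 0.65))
        k_int = int(rng.integers(1, 3))
        comps = comp_targets(int(rng.integers(1, 3)))
        int_w = rng.lognormal(0.0, 0.3, size=k_int)
        int_w = int_w / int_w.sum() * share
        comp_w = rng.lognormal(0.0, 0.3, size=len(comps))
        comp_w = comp_w / comp_w.sum() * (1.0 - share)
        glances = [(req, float(w)) for w in int_w]
        glances += [(t, float(w)) for t, w in zip(comps, comp_w)]

    final: TargetLabel | None = None
    if archetype == "NO_INTENDED_GLANCE":
        final = None
    elif match:
        final = req
    else:
        comp_targets_present = [t for t, _ in glances if t != req]
        if comp_targets_present:
            final = comp_targets_present[int(rng.integers(len(comp_targets_present)))]
        else:
            extra = comp_targets(1)[0]
            glances.append((extra, 0.08))
            final = extra
    return glances, final


def _build_segments(
    archetype: str,
    requested: str,
    competitors: list[str],
    match: bool,
    rng: np.random.Generator,
    config: GeneratorConfig,
    d_ing: int,
    d_fill: int,
    d_missing: int,
) -> tuple[list[_Seg], str | None]:
    """Assemble the episode's ordered glance segments; returns planted pattern."""
    req = TargetLabel.ingredient(requested)
    template_name: str | None = None

    base_glances, final = _ingredient_glances(
        archetype, requested, competitors, match, rng, config
    )
    block: list[_Seg] = []
    tail: list[_Seg] = []
    if archetype == "JOINT_ATTENTION":
        template_name = "JOINT_ATTENTION_INITIATION"
        block = [
            _Seg(req, weight=1.0, template=template_name),
            _Seg(PARTNER, weight=1.2, template=template_name),
            _Seg(req, weight=1.0, template=template_name),
        ]
    elif archetype == "CONFIRMATORY":
        template_name = "CONFIRMATORY_REQUEST"
        # two leading ELSEWHERE guards keep any base glance at the intended
        # target from forming a spurious joint-attention hop into the block
        block = [
            _Seg(ELSEWHERE, weight=0.5),
            _Seg(ELSEWHERE, weight=0.5),
            _Seg(PARTNER, weight=1.2, template=template_name),
            _Seg(req, weight=1.0, template=template_name),
            _Seg(PARTNER, weight=1.2, template=template_name),
        ]
    elif archetype == "GOAL_REFERENCE":
        template_name = "GOAL_REFERENCE"
        variant = int(rng.integers(3))
        if variant == 0:
            block = [
                _Seg(BREAD, weight=1.0, template=template_name),
                _Seg(req, weight=1.0, template=template_name),
            ]
        elif variant == 1:
            block = [
                _Seg(req, weight=1.0, template=template_name),
                _Seg(BREAD, weight=1.0, template=template_name),
            ]
        else:
            block = [
                _Seg(BREAD, weight=1.0, template=template_name),
                _Seg(req, weight=1.0, template=template_name),
                _Seg(BREAD, weight=1.0, template=template_name),
            ]

    if template_name is not None:
        # the block supplies the episode's closing intended glance(s); on a
        # forced mismatch a short competitor glance follows it instead
        if final is not None and final != req:
            tail = [_Seg(final, weight=0.1)]
        base_order = _order_no_adjacent([t for t, _ in base_glances], None, rng)
    else:
        base_order = _order_no_adjacent([t for t, _ in base_glances], final, rng)

    # map ordered targets back to their drawn weights (multiset semantics)
    weight_pool: dict[TargetLabel, list[float]] = {}
    for t, w in base_glances:
        weight_pool.setdefault(t, []).append(w)
    base_segs = [_Seg(t, weight=weight_pool[t].pop()) for t in base_order]

    segs = base_segs + block + tail

    # distribute the ingredient-dwell budget over all ingredient segments
    ing_idx = [i for i, s in enumerate(segs)
               if s.target.kind is TargetKind.INGREDIENT]
    if archetype == "DOMINANT":
        # the dwell-share guarantee is exact-by-construction: the intended
        # target receives at least ceil(share * budget), with a small buffer
        # absorbing any dwell later donated to adjacency repairs
        req_idx = [i for i in ing_idx if segs[i].target == req]
        other_idx = [i for i in ing_idx if segs[i].target != req]
        intended_total = min(
            d_ing - len(other_idx),
            int(np.ceil(config.dominant_dwell_share * d_ing)) + 120,
        )
        for i, d in zip(
            req_idx,
            _split_total(intended_total,
                         np.array([segs[i].weight for i in req_idx]),
                         minimum=30),
        ):
            segs[i].dwell = d
        for i, d in zip(
            other_idx,
            _split_total(d_ing - intended_total,
                         np.array([segs[i].weight for i in other_idx]),
                         minimum=1),
        ):
            segs[i].dwell = d
    else:
        ing_dwells = _split_total(
            d_ing, np.array([segs[i].weight for i in ing_idx]), minimum=30
        )
        for i, d in zip(ing_idx, ing_dwells):
            segs[i].dwell = d

    # filler budget: in-block PARTNER/BREAD/guard segments plus free
    # ELSEWHERE chunks inserted at open gaps
    fixed_idx = [i for i, s in enumerate(segs)
                 if s.target.kind is not TargetKind.INGREDIENT]
    n_free = max(1, int(round(d_fill / 600.0)))
    free_weights = rng.lognormal(0.0, 0.4, size=n_free)
    all_w = np.array([segs[i].weight for i in fixed_idx] + list(free_weights))
    fill_dwells = _split_total(d_fill, all_w, minimum=60)
    for i, d in zip(fixed_idx, fill_dwells[: len(fixed_idx)]):
        segs[i].dwell = d
    free_fillers = [
        _Seg(ELSEWHERE, dwell=d) for d in fill_dwells[len(fixed_idx):]
    ]

    # missing chunks: >= 250 ms so they can never bridge a glance merge;
    # a single sub-250 ms remainder goes to the episode start instead
    missing_chunks: list[_Seg] = []
    lead_missing: list[_Seg] = []
    if d_missing > 0:
        if d_missing < 250:
            lead_missing = [_Seg(MISSING, dwell=d_missing)]
        else:
            n_chunks = max(1, min(d_missing // 250, int(round(d_missing / 450.0))))
            for d in _split_total(
                d_missing, rng.lognormal(0.0, 0.4, size=n_chunks), minimum=250
            ):
                missing_chunks.append(_Seg(MISSING, dwell=d))

    # open gaps: anywhere except inside a planted block
    pre: list[list[_Seg]] = [[] for _ in range(len(segs) + 1)]
    open_gaps = [
        g
        for g in range(len(segs) + 1)
        if not (
            0 < g < len(segs)
            and segs[g - 1].template is not None
            and segs[g].template is not None
        )
    ]
    for chunk in free_fillers + missing_chunks:
        g = int(open_gaps[int(rng.integers(len(open_gaps)))])
        pre[g].append(chunk)

    ordered: list[_Seg] = list(lead_missing)
    for g, seg in enumerate(segs):
        ordered.extend(pre[g])
        ordered.append(seg)
    ordered.extend(pre[len(segs)])

    _repair_adjacency(ordered)
    return ordered, template_name


def _repair_adjacency(segs: list[_Seg]) -> None:
    """Separate same-target adjacent ingredient glances with a short
    ELSEWHERE glance, stealing its dwell from a filler where possible so
    archetype dwell shares survive intact."""
    i = 0
    while i < len(segs) - 1:
        a, b = segs[i], segs[i + 1]
        if (
            a.target.kind is TargetKind.INGREDIENT
            and a.target == b.target
            and a.template == b.template  # never split a planted block
        ):
            need = 60
            donor = None
            for s in segs:
                if s.target.kind is TargetKind.ELSEWHERE and s.dwell >= need + 60:
                    if donor is None or s.dwell > donor.dwell:
                        donor = s
            if donor is not None:
                donor.dwell -= need
            else:
                bigger = a if a.dwell >= b.dwell else b
                need = min(60, max(1, bigger.dwell - 1))
                bigger.dwell -= need
            segs.insert(i + 1, _Seg(ELSEWHERE, dwell=need))
        i += 1


def _segments_to_fixations(
    segs: list[_Seg], rng: np.random.Generator, config: GeneratorConfig
) -> tuple[list[FixationEvent], list[dict]]:
    """Lay segments on a gap-free timeline; split glances into fixations."""
    mean_fix = config.fixation_duration_median_ms * float(
        np.exp(config.fixation_duration_sigma**2 / 2.0)
    )
    fixations: list[FixationEvent] = []
    spans: list[dict] = []  # per-segment realized spans, for annotations
    t = 0
    for seg in segs:
        start, end = t, t + seg.dwell
        spans.append(
            {"target": seg.target, "onset_ms": start, "offset_ms": end,
             "template": seg.template}
        )
        if seg.target.kind is TargetKind.MISSING:
            fixations.append(FixationEvent(start, end, MISSING))
        else:
            k = max(1, int(round(seg.dwell / mean_fix + rng.normal(0.0, 0.3))))
            k = min(k, 6, seg.dwell)  # each fixation at least 1 ms
            if k == 1:
                cuts = []
            else:
                cuts = sorted(
                    rng.choice(np.arange(start + 1, end), size=k - 1,
                               replace=False).tolist()
                )
            bounds = [start] + [int(c) for c in cuts] + [end]
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                fixations.append(FixationEvent(lo, hi, seg.target))
        t = end
    return fixations, spans


def generate_episode(
    archetype: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
    episode_id: str = "ep0001",
) -> tuple[Episode, dict]:
    """Generate one episode of the given archetype.

    Returns the Episode and an annotation dict recording the archetype, the
    intended target, whether the final ingredient glance was forced to match
    it, and the spans of any planted template.
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    pool = config.ingredient_pool()
    lo = min(config.min_available, len(pool))
    n_avail = int(rng.integers(lo, len(pool) + 1))
    avail_idx = rng.choice(len(pool), size=n_avail, replace=False)
    available = sorted(pool[int(i)] for i in avail_idx)
    requested = available[int(rng.integers(len(available)))]
    competitors = [a for a in available if a != requested]
    if archetype != "NO_INTENDED_GLANCE" and not competitors:
        raise ValueError(f"{archetype} infeasible with a single available target")

    match = bool(rng.random() < config.last_glance_match_rate)
    duration = _draw_duration(config, rng)
    rate = float(
        np.clip(
            rng.normal(config.missing_rate,
                       config.missing_rate_jitter * config.missing_rate),
            0.0,
            0.85,
        )
    ) if config.missing_rate > 0 else 0.0
    d_missing = int(round(rate * duration))
    body = duration - d_missing
    d_ing = int(round(body * float(rng.uniform(0.50, 0.65))))
    d_fill = body - d_ing

    segs, template_name = _build_segments(
        archetype, requested, competitors, match, rng, config,
        d_ing, d_fill, d_missing,
    )
    fixations, spans = _segments_to_fixations(segs, rng, config)

    episode = Episode(
        episode_id=episode_id,
        fixations=fixations,
        request_onset_ms=duration,
        requested=requested,
        available=frozenset(available),
    )
    templates = [
        {
            "pattern": template_name,
            "onset_ms": min(s["onset_ms"] for s in spans if s["template"]),
            "offset_ms": max(s["offset_ms"] for s in spans if s["template"]),
            "focal": requested,
        }
    ] if template_name else []
    annotation = {
        "episode_id": episode_id,
        "archetype": archetype,
        "intended": requested,
        "match_enforced": None if archetype == "NO_INTENDED_GLANCE" else match,
        "planned_missing_rate": rate,
        "templates": templates,
    }
    return episode, annotation


def generate_dataset(config: GeneratorConfig) -> tuple[Dataset, list[dict]]:
    """Generate a full dataset; byte-for-byte reproducible from the seed.

    A root stream draws the archetype sequence; each episode then runs on a
    counter-based substream keyed by ``(seed, index)`` so regeneration of any
    single episode is stable.
    """
    root = np.random.default_rng(config.seed)
    names = [a for a in ARCHETYPES if config.archetype_mixture.get(a, 0.0) > 0]
    weights = np.array([config.archetype_mixture[a] for a in names])
    weights = weights / weights.sum()
    draws = root.choice(len(names), size=config.n_episodes, p=weights)

    episodes, annotations = [], []
    for i, d in enumerate(draws):
        ep_rng = np.random.default_rng([config.seed, i])
        episode, ann = generate_episode(
            names[int(d)], config, ep_rng, episode_id=f"ep{i + 1:04d}"
        )
        episodes.append(episode)
        annotations.append(ann)
    dataset = Dataset(
        episodes=episodes,
        provenance={
            "generator": "gazeintent.synth",
            "seed": config.seed,
            "n_episodes": config.n_episodes,
            "missing_rate": config.missing_rate,
            "last_glance_match_rate": config.last_glance_match_rate,
        },
    )
    return dataset, annotations


def write_dataset(
    dataset: Dataset,
    annotations: list[dict],
    outdir: str | Path,
) -> None:
    """Write the fixation dialect plus ``annotations.json`` to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fixation_table(
        dataset, outdir / "fixations.tsv", outdir / "episodes.json"
    )
    with open(outdir / "annotations.json", "w", encoding="utf-8") as fh:
        json.dump(annotations, fh, indent=1, sort_keys=True)
        fh.write("\n")
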