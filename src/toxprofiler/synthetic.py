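"""Synthetic compound libraries, plates and in vivo endpoints.

The generator plants the statistical structure the downstream analysis
assumes: compounds belong to latent mechanism classes; each class has a
prototype curve-rank activity profile (the feature space of the activity
map), a prototype binary structure fingerprint, one or two dominant
mode-of-action annotation terms, and a class-specific probability of being
toxic in each in vivo endpoint.  ``signal_strength`` in [0, 1] interpolates
between pure noise (0) and exact prototypes (1).

Seeding uses a splittable scheme (numpy SeedSequence spawn keys) so that the
draws for compound i never depend on how many compounds follow it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .qhts import RawTitration

# spawn-key component ids: keep stable so streams never collide
_K_PROFILE, _K_FP, _K_ANNOT, _K_ENDPOINT, _K_PLATE, _K_PROTO = range(6)

#: rank-noise SD at signal_strength 0 (ranks live on the integer [-9, 9] scale)
BASE_RANK_NOISE_SD = 5.0

#: fraction of compounds carrying at least one annotation term, by default
DEFAULT_ANNOTATION_COVERAGE = 0.6


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass
class SyntheticLibrary:
    """A generated compound library with planted class structure.

    ``profiles`` is a compounds x assays integer DataFrame of curve ranks in
    [-9, 9]; ``fingerprints`` a compounds x bits 0/1 DataFrame;
    ``annotations`` maps compound id to a (possibly empty) set of term ids;
    ``truth`` records the generator parameters and prototypes for
    planted-signal recovery tests.
    """

    compounds: list[str]
    latent_class: dict[str, int]
    profiles: pd.DataFrame
    fingerprints: pd.DataFrame
    annotations: dict[str, set[str]]
    truth: dict = field(default_factory=dict)

    @property
    def n_classes(self) -> int:
        return int(self.truth["n_classes"])

    def class_of(self, compound: str) -> int:
        return self.latent_class[compound]


@dataclass(frozen=True)
class EndpointSpec:
    """Recipe for one synthetic in vivo endpoint.

    ``endpoint_type``: "dose" (LD50-like mg/kg values thresholded at 300),
    "score" (continuous, lower = more toxic, top-35-percentile rule) or
    "composite" (majority vote over ``components``).
    ``class_toxicity_prob`` maps latent class -> probability toxic.
    """

    name: str
    endpoint_type: str  # dose | score | composite
    class_toxicity_prob: Mapping[int, float] = field(default_factory=dict)
    replicate_rate: float = 0.0
    replicate_noise: float = 0.0
    components: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.endpoint_type not in ("dose", "score", "composite"):
            raise ValueError(f"unknown endpoint_type {self.endpoint_type!r}")
        for p in (self.replicate_rate, self.replicate_noise,
                  *self.class_toxicity_prob.values()):
            if not 0.0 <= float(p) <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.endpoint_type == "composite" and len(self.components) < 2:
            raise ValueError("composite endpoints need >= 2 components")


def generate_library(
    n_compounds: int,
    n_classes: int,
    n_assays: int = 30,
    n_bits: int = 256,
    signal_strength: float = 0.8,
    seed: int = 0,
    annotation_coverage: float = DEFAULT_ANNOTATION_COVERAGE,
    fingerprint_flip: float | None = None,
    n_terms: int | None = None,
) -> SyntheticLibrary:
    """Generate a compound library with planted mechanism classes.

    Each class gets a prototype rank vector (entries drawn from the curve
    rank scale), a prototype fingerprint, and 1-2 dominant annotation
    terms.  A compound's profile is round(s * prototype + eps), with eps
    Gaussian of SD BASE_RANK_NOISE_SD * (1 - s), clipped to [-9, 9]: at
    s=1 members of a class are identical, at s=0 profiles are class-free
    noise.  Fingerprint bits flip independently with probability
    ``fingerprint_flip`` (default 0.5 * (1 - s)).  Annotated compounds
    (fraction ``annotation_coverage``) receive a dominant term of their
    class with probability s, otherwise a uniformly random term.
    """
    if n_compounds <= 0 or n_classes <= 0 or n_assays <= 0 or n_bits <= 0:
        raise ValueError("sizes must be positive")
    if n_compounds < n_classes:
        raise ValueError("need at least one compound per class")
    if not 0.0 <= signal_strength <= 1.0:
        raise ValueError("signal_strength must lie in [0, 1]")
    s = float(signal_strength)
    flip = 0.5 * (1.0 - s) if fingerprint_flip is None else float(fingerprint_flip)
    n_terms = n_terms if n_terms is not None else max(3 * n_classes, 8)

    proto_rng = _rng(seed, _K_PROTO)
    rank_scale = np.array([-9, -8, -6, -5, -3, -1, 0, 1, 3, 5, 6, 8, 9])
    prototypes = proto_rng.choice(rank_scale, size=(n_classes, n_assays))
    proto_fp = (proto_rng.random((n_classes, n_bits)) < 0.3).astype(np.int8)
    terms = [f"T{i:03d}" for i in range(n_terms)]
    # 1-2 dominant terms per class, drawn without replacement when possible
    order = proto_rng.permutation(n_terms)
    dominant: list[list[str]] = []
    pos = 0
    for k in range(n_classes):
        take = int(proto_rng.integers(1, 3))
        if pos + take > n_terms:
            pos = 0
        dominant.append([terms[j] for j in order[pos:pos + take]])
        pos += take

    compounds = [f"C{i:05d}" for i in range(n_compounds)]
    classes = {
        cid: int(_rng(seed, _K_PROFILE, i).integers(n_classes))
        for i, cid in enumerate(compounds)
    }

    prof = np.empty((n_compounds, n_assays), dtype=np.int64)
    fps = np.empty((n_compounds, n_bits), dtype=np.int8)
    annotations: dict[str, set[str]] = {}
    for i, cid in enumerate(compounds):
        k = classes[cid]
        rng_p = _rng(seed, _K_PROFILE, i)
        rng_p.integers(n_classes)  # consumed above for the class draw
        noise = rng_p.normal(0.0, BASE_RANK_NOISE_SD * (1.0 - s), n_assays)
        prof[i] = np.clip(np.rint(s * prototypes[k] + noise), -9, 9)

        rng_f = _rng(seed, _K_FP, i)
        flips = rng_f.random(n_bits) < flip
        fps[i] = np.where(flips, 1 - proto_fp[k], proto_fp[k])

        rng_a = _rng(seed, _K_ANNOT, i)
        annotations[cid] = set()
        if rng_a.random() < annotation_coverage:
            if rng_a.random() < s:
                term = dominant[k][int(rng_a.integers(len(dominant[k])))]
            else:
                term = terms[int(rng_a.integers(n_terms))]
            annotations[cid] = {term}

    profiles = pd.DataFrame(
        prof, index=compounds,
        columns=[f"assay{j:02d}" for j in range(n_assays)],
    )
    fingerprints = pd.DataFrame(
        fps, index=compounds, columns=[f"bit{j:04d}" for j in range(n_bits)]
    )
    truth = {
        "n_classes": n_classes,
        "signal_strength": s,
        "annotation_coverage": annotation_coverage,
        "fingerprint_flip": flip,
        "prototypes": prototypes,
        "prototype_fingerprints": proto_fp,
        "dominant_terms": {k: list(v) for k, v in enumerate(dominant)},
        "seed": seed,
    }
    return SyntheticLibrary(
        compounds=compounds, latent_class=classes, profiles=profiles,
        fingerprints=fingerprints, annotations=annotations, truth=truth,
    )


def generate_plate_set(
    true_ac50: float,
    true_efficacy: float,
    hill_slope: float = 1.0,
    n_conc: int = 15,
    conc_range: tuple[float, float] = (1e-9, 1e-4),
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
    compound_id: str = "C00000",
    assay_mode: str = "agonist",
    v_dmso: float = 1000.0,
    v_pos: float = 5000.0,
    n_control_wells: int = 16,
) -> list[RawTitration]:
    """Simulate replicate raw titrations of one compound.

    Raw reads follow a four-parameter Hill curve in log concentration
    (baseline 0%, plateau ``true_efficacy``%) mapped onto raw signal units
    between the DMSO level ``v_dmso`` (0%) and the positive-control level
    ``v_pos`` (100%), plus Gaussian noise of SD ``noise_sd`` percent.
    Control wells are simulated too, so the returned titrations carry
    noisy (median-summarized) control anchors and normalization is
    genuinely exercised.  Replicates differ only by their noise stream.
    """
    low, high = conc_range
    if not low < high:
        raise ValueError("conc_range must satisfy low < high")
    if n_conc < 4:
        raise ValueError("need at least 4 concentrations")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if n_replicates <= 0:
        raise ValueError("n_replicates must be positive")
    conc = np.logspace(np.log10(low), np.log10(high), n_conc)
    span = v_pos - v_dmso
    with np.errstate(over="ignore"):
        pct_true = true_efficacy / (1.0 + (true_ac50 / conc) ** hill_slope)

    out: list[RawTitration] = []
    for rep in range(n_replicates):
        rng = _rng(seed, _K_PLATE, rep)
        raw = v_dmso + (pct_true + rng.normal(0, noise_sd, n_conc)) / 100.0 * span
        dmso_wells = v_dmso + rng.normal(0, noise_sd, n_control_wells) / 100.0 * span
        pos_wells = v_pos + rng.normal(0, noise_sd, n_control_wells) / 100.0 * span
        out.append(
            RawTitration(
                compound_id=compound_id,
                concentrations=conc,
                raw_reads=raw,
                pos_control_median=float(np.median(pos_wells)),
                dmso_median=float(np.median(dmso_wells)),
                assay_mode=assay_mode,  # type: ignore[arg-type]
            )
        )
    return out


def generate_endpoints(
    library: SyntheticLibrary,
    specs: Sequence[EndpointSpec],
    seed: int = 0,
):
    """Generate an in vivo endpoint table for a synthetic library.

    Dose endpoints draw log10 LD50-like values from N(1.9, 0.35) for toxic
    compounds (clipped below 300 mg/kg) and N(3.1, 0.35) for non-toxic
    (clipped above 300), so values straddle the 300 mg/kg rule.  Score
    endpoints draw N(-1, 1) / N(+1, 1) (lower = more toxic).  A fraction
    ``replicate_rate`` of compounds receives a second replicate, which
    copies the first measurement unless the latent call flips
    (probability ``replicate_noise``), in which case it is redrawn from
    the flipped distribution.  Composite specs emit no rows; they are
    registered in the metadata with their components.
    """
    from .endpoints import EndpointMeta, EndpointTable

    if not specs:
        raise ValueError("specs must be non-empty")
    names = {sp.name for sp in specs}
    n_classes = library.n_classes
    rows: list[tuple[str, str, float, int]] = []
    meta: dict[str, EndpointMeta] = {}
    for j, sp in enumerate(sorted(specs, key=lambda s: s.name)):
        for k in sp.class_toxicity_prob:
            if not 0 <= int(k) < n_classes:
                raise ValueError(f"endpoint {sp.name!r} references unknown class {k}")
        if sp.endpoint_type == "composite":
            missing = [c for c in sp.components if c not in names]
            if missing:
                raise ValueError(
                    f"composite {sp.name!r} references unknown components {missing}"
                )
            meta[sp.name] = EndpointMeta(
                name=sp.name, endpoint_type="composite",
                components=tuple(sp.components),
            )
            continue
        meta[sp.name] = EndpointMeta(name=sp.name, endpoint_type=sp.endpoint_type)
        for i, cid in enumerate(library.compounds):
            rng = _rng(seed, _K_ENDPOINT, j, i)
            p = float(sp.class_toxicity_prob.get(library.latent_class[cid], 0.0))
            toxic = rng.random() < p
            value = _draw_value(rng, sp.endpoint_type, toxic)
            rows.append((cid, sp.name, value, 1))
            if rng.random() < sp.replicate_rate:
                if rng.random() < sp.replicate_noise:
                    value2 = _draw_value(rng, sp.endpoint_type, not toxic)
                else:
                    value2 = value
                rows.append((cid, sp.name, value2, 2))
    entries = pd.DataFrame(
        rows, columns=["compound_id", "endpoint", "value", "replicate_index"]
    )
    return EndpointTable(entries=entries, meta=meta)


def _draw_value(rng: np.random.Generator, endpoint_type: str, toxic: bool) -> float:
    if endpoint_type == "dose":
        if toxic:
            return float(min(10.0 ** rng.normal(1.9, 0.35), 299.0))
        return float(max(10.0 ** rng.normal(3.1, 0.35), 301.0))
    # score: lower = more toxic
    return float(rng.normal(-1.0 if toxic else 1.0, 1.0))
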