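"""Synthetic data with the statistical structure the pipeline assumes.

Four generators cover the pipeline's inputs end to end:

* a per-gene pull-down/kinetics table with planted targets, sponge candidates
  and decoy classes (negative-binomial pull-down counts, log-normal basal
  expression, drifting kinetic logFC);
* kinetic logFC trajectories over a transfection time course;
* transcripts with planted canonical and bulged seed sites and an exact
  ground-truth site registry (background sequence is rejection-sampled so no
  accidental site can occur);
* proportional-hazards survival cohorts with a small set of truly prognostic
  genes.

Every generator is deterministic under its seed, and each returns the hidden
truth (class labels, site registry, hazard coefficients) *separately* from the
observable data, so downstream code can be tested against a known answer
without ever seeing it.

Label consistency contract: a gene's observables are resampled (within its
class distribution) until they fall on the correct side of every filter
threshold for its truth label, so the planted class structure is recovered
exactly by the filter cascade. The defaults mirror the kinetic class mix of
the source experiment: ~88% stable, ~5% down-regulated, ~7% up-regulated
genes, with cascade class sizes scaled from 14,842 profiled genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mre import MIR16, Mirna, bulged_site_strings, canonical_site_strings
from .survival import SurvivalCohort

__all__ = [
    "SimulationSpec",
    "SurvivalSimSpec",
    "SitePlanEntry",
    "simulate_interactome_table",
    "simulate_kinetic_logfc",
    "simulate_transcripts",
    "simulate_survival_cohort",
    "EXPECTED_LABELS",
]

# cascade class sizes of the source experiment, per profiled gene, used to
# scale the planted-structure defaults: 476 window-b genes of which 327
# survive the control filter; 497 window-c genes of which 403 survive, 57 of
# those passing the basal filter; 14,842 genes in total.
_REF_TOTAL = 14842
_REF = {
    "true_target": 327,
    "decoy_high_ctr_down": 476 - 327,
    "true_sponge": 57,
    "decoy_low_basal": 403 - 57,
    "decoy_high_ctr_up": 497 - 403,
}

#: final_label the filter cascade must assign to each truth class
EXPECTED_LABELS = {
    "true_target": "target",
    "decoy_high_ctr_down": "excluded_false_positive",
    "decoy_high_ctr_up": "excluded_false_positive",
    "true_sponge": "sponge_candidate",
    "decoy_low_basal": "interactant_up",
    "down_background": "none",
    "up_background": "none",
    "stable": "none",
}

_KINETIC_OF_CLASS = {
    "true_target": "down",
    "decoy_high_ctr_down": "down",
    "down_background": "down",
    "true_sponge": "up",
    "decoy_high_ctr_up": "up",
    "decoy_low_basal": "up",
    "up_background": "up",
    "stable": "stable",
}


def _scaled(n_genes: int, cls: str) -> int:
    return max(1, round(n_genes * _REF[cls] / _REF_TOTAL))


@dataclass
class SimulationSpec:
    """Conditions for the pull-down / kinetics table generator.

    Class-size fields left as None default to the source experiment's
    structure scaled to ``n_genes``. ``frac_down``/``frac_up`` are the overall
    kinetic class fractions (planted interactants included).
    """

    n_genes: int
    frac_down: float = 0.05
    frac_up: float = 0.07
    n_true_targets: int | None = None
    n_true_sponges: int | None = None
    n_decoy_high_ctr_down: int | None = None
    n_decoy_high_ctr_up: int | None = None
    n_decoy_low_basal: int | None = None
    pulldown_dispersion: float = 0.3
    enrichment_factor: float = 8.0
    ctr_background_rate: float = 30.0
    basal_mean_log: float = 3.0
    logfc_noise_sd: float = 0.15
    logfc_amplitude: float = 1.2
    timepoints: tuple[float, ...] = (0.0, 6.0, 12.0, 24.0, 48.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not (0 <= self.frac_down <= 1 and 0 <= self.frac_up <= 1):
            raise ValueError("class fractions must be in [0, 1]")
        if self.frac_down + self.frac_up > 1:
            raise ValueError("frac_down + frac_up must not exceed 1")
        if self.pulldown_dispersion <= 0:
            raise ValueError("pulldown_dispersion must be positive")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        if self.ctr_background_rate < 0:
            raise ValueError("ctr_background_rate must be non-negative")
        tps = tuple(float(t) for t in self.timepoints)
        if len(tps) < 2 or tps[0] != 0 or any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must start at 0 and be strictly increasing")
        if any(t < 0 for t in tps):
            raise ValueError("timepoints must be non-negative")
        object.__setattr__(self, "timepoints", tps)
        if self.n_true_targets is None:
            self.n_true_targets = _scaled(self.n_genes, "true_target")
        if self.n_true_sponges is None:
            self.n_true_sponges = _scaled(self.n_genes, "true_sponge")
        if self.n_decoy_high_ctr_down is None:
            self.n_decoy_high_ctr_down = _scaled(self.n_genes, "decoy_high_ctr_down")
        if self.n_decoy_high_ctr_up is None:
            self.n_decoy_high_ctr_up = _scaled(self.n_genes, "decoy_high_ctr_up")
        if self.n_decoy_low_basal is None:
            self.n_decoy_low_basal = _scaled(self.n_genes, "decoy_low_basal")
        n_down = round(self.frac_down * self.n_genes)
        n_up = round(self.frac_up * self.n_genes)
        if self.n_true_targets + self.n_decoy_high_ctr_down > n_down:
            raise ValueError(
                f"planted down-class genes ({self.n_true_targets} targets + "
                f"{self.n_decoy_high_ctr_down} decoys) exceed the {n_down} "
                f"down-regulated genes implied by frac_down"
            )
        if self.n_true_sponges + self.n_decoy_high_ctr_up + self.n_decoy_low_basal > n_up:
            raise ValueError(
                f"planted up-class genes exceed the {n_up} up-regulated genes "
                f"implied by frac_up"
            )


def _nb(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Negative-binomial counts with the mean/dispersion parameterisation
    Var = mu + dispersion * mu^2 (standard for overdispersed RNA-seq counts)."""
    if mean <= 0:
        return np.zeros(size, dtype=int)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def _nb_constrained(
    rng: np.random.Generator,
    mean: float,
    dispersion: float,
    size: int,
    low: int | None = None,
    high: int | None = None,
    max_tries: int = 200,
) -> np.ndarray:
    """NB counts conditioned on low < x (if low) and x <= high (if high).

    Rejection-resamples per element; after ``max_tries`` the stragglers are
    clamped just inside the admissible range (keeps the generator total)."""
    x = _nb(rng, mean, dispersion, size)
    for _ in range(max_tries):
        bad = np.zeros(size, dtype=bool)
        if low is not None:
            bad |= x <= low
        if high is not None:
            bad |= x > high
        if not bad.any():
            return x
        x[bad] = _nb(rng, mean, dispersion, int(bad.sum()))
    if low is not None:
        x = np.maximum(x, low + 1)
    if high is not None:
        x = np.minimum(x, high)
    return x


def simulate_kinetic_logfc(
    spec: SimulationSpec,
    class_labels: Sequence[str],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Kinetic logFC matrix (genes x timepoints) for given kinetic classes.

    Each gene's expected trajectory starts at 0 and ramps linearly to
    +/- ``logfc_amplitude`` (up/down) or stays at 0 (stable); i.i.d. Gaussian
    noise with SD ``logfc_noise_sd`` is added at every timepoint. Rows whose
    noisy late-window mean (two latest timepoints) would cross the +/-0.5
    class boundary are re-noised, so the returned classes are exact.
    """
    labels = list(class_labels)
    for lab in labels:
        if lab not in ("down", "stable", "up"):
            raise ValueError(f"unknown kinetic class {lab!r}")
    tps = np.asarray(spec.timepoints, dtype=float)
    if np.any(tps < 0):
        raise ValueError("negative timepoints are not allowed")
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    n = len(labels)
    amp = {"down": -spec.logfc_amplitude, "stable": 0.0, "up": spec.logfc_amplitude}
    drift = np.array([amp[lab] for lab in labels])[:, None] * (tps / tps[-1])[None, :]
    late = slice(len(tps) - 2, len(tps))
    thr = 0.5

    def _ok(mat: np.ndarray) -> np.ndarray:
        late_mean = mat[:, late].mean(axis=1)
        ok = np.empty(n, dtype=bool)
        for i, lab in enumerate(labels):
            if lab == "down":
                ok[i] = late_mean[i] < -thr
            elif lab == "up":
                ok[i] = late_mean[i] > thr
            else:
                ok[i] = -thr < late_mean[i] < thr
        return ok

    mat = drift + rng.normal(0.0, spec.logfc_noise_sd, size=(n, len(tps)))
    for _ in range(200):
        ok = _ok(mat)
        if ok.all():
            break
        bad = ~ok
        mat[bad] = drift[bad] + rng.normal(
            0.0, spec.logfc_noise_sd, size=(int(bad.sum()), len(tps))
        )
    else:
        mat[~_ok(mat)] = drift[~_ok(mat)]  # noise-free fallback, always in class
    return pd.DataFrame(mat, columns=[f"logfc_{t:g}h" for t in tps])


def simulate_interactome_table(
    spec: SimulationSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene observable table plus the hidden truth labels.

    Returns
    -------
    table : DataFrame with columns gene_id, reads_mir16, reads_mirctr,
        basal_expr, logfc_<t>h ... (the observables the cascade sees)
    truth : DataFrame with columns gene_id, truth_class, kinetic_class,
        expected_label (never to be consumed by pipeline code)
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_genes
    n_down = round(spec.frac_down * n)
    n_up = round(spec.frac_up * n)

    classes: list[str] = []
    classes += ["true_target"] * spec.n_true_targets
    classes += ["decoy_high_ctr_down"] * spec.n_decoy_high_ctr_down
    classes += ["down_background"] * (n_down - spec.n_true_targets - spec.n_decoy_high_ctr_down)
    classes += ["true_sponge"] * spec.n_true_sponges
    classes += ["decoy_high_ctr_up"] * spec.n_decoy_high_ctr_up
    classes += ["decoy_low_basal"] * spec.n_decoy_low_basal
    classes += ["up_background"] * (
        n_up - spec.n_true_sponges - spec.n_decoy_high_ctr_up - spec.n_decoy_low_basal
    )
    classes += ["stable"] * (n - len(classes))
    classes_arr = np.array(classes)
    rng.shuffle(classes_arr)

    ip_mean = spec.enrichment_factor * spec.ctr_background_rate
    disp = spec.pulldown_dispersion
    reads_ip = np.zeros(n, dtype=int)
    reads_ctr = np.zeros(n, dtype=int)
    basal = np.zeros(n)

    bound = np.isin(
        classes_arr,
        ["true_target", "true_sponge", "decoy_high_ctr_down", "decoy_high_ctr_up", "decoy_low_basal"],
    )
    high_ctr = np.isin(classes_arr, ["decoy_high_ctr_down", "decoy_high_ctr_up"])

    # pull-down counts: bait-bound genes are enriched and must clear the
    # 100-read window; everything else stays at (or below) background.
    # With enrichment_factor == 1 there is no enrichment and no window
    # guarantee: both baits draw from the same background distribution.
    if spec.enrichment_factor > 1:
        reads_ip[bound] = _nb_constrained(rng, ip_mean, disp, int(bound.sum()), low=100)
        reads_ip[~bound] = _nb_constrained(
            rng, spec.ctr_background_rate, disp, int((~bound).sum()), high=100
        )
    else:
        reads_ip[:] = _nb(rng, spec.ctr_background_rate, disp, n)
    # control-bait counts: decoys are "sticky" (highly detected with the
    # control bait); all other genes stay under the 500-read exclusion
    reads_ctr[high_ctr] = _nb_constrained(rng, 4 * 500.0, disp, int(high_ctr.sum()), low=500)
    reads_ctr[~high_ctr] = _nb_constrained(
        rng, spec.ctr_background_rate, disp, int((~high_ctr).sum()), high=500
    )

    # basal expression: log-normal; sponges must exceed 10, low-basal decoys must not
    basal = rng.lognormal(spec.basal_mean_log, 1.0, size=n)
    sponge = classes_arr == "true_sponge"
    lowb = classes_arr == "decoy_low_basal"
    for _ in range(200):
        bad = (sponge & (basal <= 10.0)) | (lowb & (basal > 10.0))
        if not bad.any():
            break
        basal[bad] = rng.lognormal(spec.basal_mean_log, 1.0, size=int(bad.sum()))
    basal[sponge & (basal <= 10.0)] = 10.0 + rng.gamma(2.0, 5.0, int((sponge & (basal <= 10.0)).sum()))
    basal[lowb & (basal > 10.0)] = rng.uniform(0.5, 10.0, int((lowb & (basal > 10.0)).sum()))

    kinetic = np.array([_KINETIC_OF_CLASS[c] for c in classes_arr])
    logfc = simulate_kinetic_logfc(spec, kinetic, rng=rng)

    gene_ids = [f"G{i + 1:05d}" for i in range(n)]
    table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "reads_mir16": reads_ip,
            "reads_mirctr": reads_ctr,
            "basal_expr": np.round(basal, 4),
        }
    )
    table = pd.concat([table, logfc], axis=1)
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "truth_class": classes_arr,
            "kinetic_class": kinetic,
            "expected_label": [EXPECTED_LABELS[c] for c in classes_arr],
        }
    )
    return table, truth


# ---------------------------------------------------------------------------
# transcripts with planted sites


@dataclass
class SitePlanEntry:
    """Planting plan for one transcript class.

    ``canonical_fraction`` / ``bulged_fraction`` of the class's transcripts
    get (independently chosen) planted sites; counts are exact
    (``round(fraction * n)``), not binomial, so planted fractions are
    recovered exactly. ``positions`` optionally fixes the insertion start for
    every planted site (one site per transcript in that case).
    """

    n_transcripts: int
    canonical_fraction: float = 0.0
    canonical_type: str = "8mer"
    bulged_fraction: float = 0.0
    sites_per_transcript: int = 1
    positions: tuple[int, ...] | None = None


def _random_dna(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


_BASES = np.array(list("ACGT"))


def _naive_motif_occurrences(seq: str, motifs: Iterable[str]) -> list[tuple[int, int, str]]:
    out = []
    for m in motifs:
        start = seq.find(m)
        while start != -1:
            out.append((start, start + len(m), m))
            start = seq.find(m, start + 1)
    return sorted(out)


def simulate_transcripts(
    n: int,
    length: int,
    site_plan: Mapping[str, SitePlanEntry],
    rng_seed: int = 0,
    mirna: Mirna = MIR16,
    bulge_position: int = 5,
    allowed_bases: tuple[str, ...] = ("G", "T", "A"),
) -> tuple[dict[str, str], pd.DataFrame, dict[str, str]]:
    """Random transcripts with planted seed sites and an exact site registry.

    Background sequence is uniform random DNA with every site-equivalent
    substring rejected and resampled, so the registry (one row per planted
    site: transcript_id, start, end, site_type, inserted_base) is the exact
    ground truth of site occurrences. Transcripts not covered by the plan are
    site-free background.

    Returns ``(sequences, registry, transcript_class)``.
    """
    canon = canonical_site_strings(mirna)
    bulged = bulged_site_strings(mirna, bulge_position, allowed_bases)
    max_site = max(len(s) for s in list(canon.values()) + list(bulged.values()))
    if length < max_site + 2:
        raise ValueError(
            f"transcript length {length} too short for sites up to {max_site} nt"
        )
    planned_total = sum(e.n_transcripts for e in site_plan.values())
    if planned_total > n:
        raise ValueError(f"site plan covers {planned_total} transcripts but n={n}")

    # forbid the 6mer core anywhere in the background: every canonical and
    # bulged motif contains it, so excluding it (plus the bulged motifs, which
    # do not contain the 6mer contiguously) guarantees a site-free background
    forbidden = sorted(set(canon.values()) | set(bulged.values()))

    rng = np.random.default_rng(rng_seed)
    seqs: dict[str, str] = {}
    registry_rows: list[dict] = []
    classes: dict[str, str] = {}

    # assignment of transcripts to classes, in plan order, remainder background
    assignment: list[tuple[str, SitePlanEntry | None]] = []
    for label, entry in site_plan.items():
        assignment += [(label, entry)] * entry.n_transcripts
    assignment += [("background", None)] * (n - planned_total)

    # which transcripts of each class get sites (exact counts)
    plant_canonical: dict[int, str] = {}
    plant_bulged: set[int] = set()
    idx = 0
    for label, entry in site_plan.items():
        members = list(range(idx, idx + entry.n_transcripts))
        idx += entry.n_transcripts
        n_can = int(round(entry.canonical_fraction * entry.n_transcripts))
        n_bul = int(round(entry.bulged_fraction * entry.n_transcripts))
        if entry.canonical_type not in canon:
            raise ValueError(f"unknown canonical site type {entry.canonical_type!r}")
        for t in rng.choice(members, size=n_can, replace=False) if n_can else []:
            plant_canonical[int(t)] = entry.canonical_type
        for t in rng.choice(members, size=n_bul, replace=False) if n_bul else []:
            plant_bulged.add(int(t))

    for i in range(n):
        label, entry = assignment[i]
        tid = f"TX{i + 1:05d}"
        classes[tid] = label
        planned: list[tuple[int, int, str, str | None]] = []  # start, end, type, inserted

        for attempt in range(200):
            arr = _random_dna(rng, length)
            seq = "".join(_BASES[arr])
            # scrub accidental motifs from the background
            for _ in range(50):
                occ = _naive_motif_occurrences(seq, forbidden)
                if not occ:
                    break
                arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
                for s, e, _m in occ:
                    arr[s:e] = _BASES[rng.integers(0, 4, size=e - s)]
                seq = "".join(arr)
            planned = []
            # plant sites by overwriting (length preserved)
            inserts: list[tuple[int, str, str, str | None]] = []
            n_sites = entry.sites_per_transcript if entry else 1
            if i in plant_canonical:
                s = canon[plant_canonical[i]]
                for k in range(n_sites):
                    inserts.append((k, s, plant_canonical[i], None))
            if i in plant_bulged:
                base = str(rng.choice([b for b in bulged]))
                for k in range(n_sites):
                    inserts.append((k, bulged[base], "bulged", base))
            if inserts:
                if entry is not None and entry.positions is not None:
                    positions = list(entry.positions)
                    if len(positions) < len(inserts):
                        raise ValueError("fewer positions than planted sites")
                else:
                    positions = None
                chars = list(seq)
                used: list[tuple[int, int]] = []
                ok = True
                for j, (_k, motif, stype, ibase) in enumerate(inserts):
                    if positions is not None:
                        p = positions[j]
                        if p < 0 or p + len(motif) > length:
                            raise ValueError(
                                f"site of length {len(motif)} does not fit at {p} "
                                f"in transcript of length {length}"
                            )
                    else:
                        for _ in range(100):
                            p = int(rng.integers(1, length - len(motif) - 1))
                            if all(e2 <= p - 8 or s2 >= p + len(motif) + 8 for s2, e2 in used):
                                break
                        else:
                            ok = False
                            break
                    chars[p : p + len(motif)] = motif
                    used.append((p, p + len(motif)))
                    planned.append((p, p + len(motif), stype, ibase))
                if not ok:
                    continue
                seq = "".join(chars)
            # verify: realized motif occurrences == planted ones (planting can
            # create new matches at junctions; resample if so)
            occ = _naive_motif_occurrences(seq, forbidden)
            expected = _expected_occurrences(planned, canon, bulged)
            if sorted((s, e) for s, e, _m in occ) == sorted(expected):
                break
        else:  # pragma: no cover - rejection loop essentially always succeeds
            raise RuntimeError(f"could not build a clean transcript for {tid}")

        seqs[tid] = seq
        for s, e, stype, ibase in sorted(planned):
            registry_rows.append(
                {
                    "transcript_id": tid,
                    "start": s,
                    "end": e,
                    "site_type": stype,
                    "inserted_base": ibase if ibase is not None else "",
                }
            )

    registry = pd.DataFrame(
        registry_rows,
        columns=["transcript_id", "start", "end", "site_type", "inserted_base"],
    )
    return seqs, registry, classes


def _expected_occurrences(
    planned: list[tuple[int, int, str, str | None]],
    canon: Mapping[str, str],
    bulged: Mapping[str, str],
) -> list[tuple[int, int]]:
    """Motif-string occurrence intervals a planted site legitimately produces."""
    out: list[tuple[int, int]] = []
    for s, e, stype, ibase in planned:
        if stype == "bulged":
            out.append((s, e))
            continue
        # a canonical site contains occurrences of the shorter canonical strings
        site = canon[stype]
        for m in canon.values():
            k = site.find(m)
            while k != -1:
                out.append((s + k, s + k + len(m)))
                k = site.find(m, k + 1)
        for m in bulged.values():
            k = site.find(m)
            while k != -1:
                out.append((s + k, s + k + len(m)))
                k = site.find(m, k + 1)
    return out


# ---------------------------------------------------------------------------
# survival cohorts


@dataclass
class SurvivalSimSpec:
    """Conditions for the proportional-hazards cohort generator."""

    n_samples: int
    n_genes: int
    prognostic_genes: Mapping[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.02
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be non-negative")
        for g, b in self.prognostic_genes.items():
            if not np.isfinite(b):
                raise ValueError(f"non-finite hazard coefficient for {g}")


def simulate_survival_cohort(
    spec: SurvivalSimSpec,
    gene_names: Sequence[str] | None = None,
) -> tuple[SurvivalCohort, dict[str, float]]:
    """Exponential proportional-hazards cohort with planted prognostic genes.

    Expression is standard normal per gene; event times are exponential with
    hazard ``baseline_hazard * exp(sum coef * expression)``; censoring is an
    independent exponential at ``censoring_rate`` (0 = no censoring).

    Returns the cohort and the full gene->coefficient map (zeros for
    non-prognostic genes).
    """
    rng = np.random.default_rng(spec.rng_seed)
    if gene_names is None:
        gene_names = [f"S{i + 1:04d}" for i in range(spec.n_genes)]
    gene_names = list(gene_names)
    if len(gene_names) != spec.n_genes:
        raise ValueError("gene_names length must equal n_genes")
    unknown = set(spec.prognostic_genes) - set(gene_names)
    if unknown:
        raise ValueError(f"prognostic genes not in cohort: {sorted(unknown)}")

    X = rng.standard_normal((spec.n_samples, spec.n_genes))
    beta = np.array([spec.prognostic_genes.get(g, 0.0) for g in gene_names])
    eta = X @ beta
    hazard = spec.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / hazard)
    if spec.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / spec.censoring_rate, size=spec.n_samples)
    else:
        t_cens = np.full(spec.n_samples, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    sample_ids = [f"P{i + 1:04d}" for i in range(spec.n_samples)]
    cohort = SurvivalCohort(
        sample_ids=sample_ids,
        time=time,
        event=event,
        expression=pd.DataFrame(X, index=sample_ids, columns=gene_names),
    )
    return cohort, {g: float(b) for g, b in zip(gene_names, beta)}
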