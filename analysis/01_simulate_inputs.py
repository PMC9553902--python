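#!/usr/bin/env python
"""Generate the synthetic study inputs.

Produces a 1,500-gene pull-down/kinetics table with the planted class
structure (scaled from the cascade counts of the source experiment), a set of
transcripts with planted canonical and bulged miR-16 sites, and a pair of
proportional-hazards survival cohorts over the sponge-candidate genes.

Small summaries go to results/; the full tables (inputs for the later
scripts) go to scratch/analysis/.
"""

import json
from pathlib import Path

from spongescope.io import write_cohort, write_fasta, write_gene_table, write_tsv
from spongescope.simulate import (
    SimulationSpec,
    SitePlanEntry,
    SurvivalSimSpec,
    simulate_interactome_table,
    simulate_survival_cohort,
    simulate_transcripts,
)

SEED = 20221006
ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    spec = SimulationSpec(n_genes=1500, rng_seed=SEED)
    table, truth = simulate_interactome_table(spec)
    write_gene_table(table, DATA / "genes.tsv", {"seed": SEED})
    write_tsv(truth, DATA / "truth.tsv", {"seed": SEED})
    planted = truth.truth_class.value_counts().to_dict()
    print(f"gene table: {len(table)} genes, planted classes {planted}")

    plan = {
        "target": SitePlanEntry(n_transcripts=400, canonical_fraction=0.30,
                                canonical_type="8mer"),
        "sponge": SitePlanEntry(n_transcripts=300, canonical_fraction=0.02,
                                bulged_fraction=1.0),
    }
    seqs, registry, classes = simulate_transcripts(1000, 200, plan, rng_seed=SEED + 1)
    write_fasta(seqs, DATA / "transcripts.fasta")
    write_tsv(registry, DATA / "site_registry.tsv", {"seed": SEED + 1})
    (DATA / "transcript_classes.json").write_text(
        json.dumps(classes, indent=2, sort_keys=True) + "\n"
    )
    print(f"transcripts: {len(seqs)} sequences, {len(registry)} planted sites")

    prognostic = {"S0001": 1.0, "S0002": -1.0}
    train, _ = simulate_survival_cohort(
        SurvivalSimSpec(n_samples=200, n_genes=50, prognostic_genes=prognostic,
                        rng_seed=SEED + 2)
    )
    valid, _ = simulate_survival_cohort(
        SurvivalSimSpec(n_samples=300, n_genes=50, prognostic_genes=prognostic,
                        rng_seed=SEED + 3)
    )
    write_cohort(train, DATA / "cohort_train.tsv", {"seed": SEED + 2})
    write_cohort(valid, DATA / "cohort_valid.tsv", {"seed": SEED + 3})
    print(
        f"cohorts: train n={train.n_samples} ({int(train.event.sum())} events), "
        f"valid n={valid.n_samples} ({int(valid.event.sum())} events); "
        f"prognostic genes {prognostic}"
    )

    summary = {
        "seed": SEED,
        "n_genes": len(table),
        "planted_classes": planted,
        "n_transcripts": len(seqs),
        "n_planted_sites": int(len(registry)),
        "cohort_train_n": train.n_samples,
        "cohort_valid_n": valid.n_samples,
        "prognostic_genes": prognostic,
    }
    (RESULTS / "01_simulation_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    print(f"summary -> {RESULTS / '01_simulation_summary.json'}")


if __name__ == "__main__":
    main()
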