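"""Shared fixtures: tiny handcrafted ORFs and seeded simulations.

The expensive simulations (parameter recovery across seeds, planted
metagene stall) are session-scoped so module tests and the acceptance
suite share one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ribopause as rp

RECOVERY_SPECS = (
    rp.StallSpec("CGA", "CGA", enrichment_short=50.0),
    rp.StallSpec("GTA", "GGA", enrichment_short=10.0),
    rp.StallSpec("CTT", "TCA", enrichment_short=2.0),
)
RECOVERY_SEEDS = (101, 102, 103)


def pipeline_core(
    reads: pd.DataFrame, orfs, min_density: float = 0.5
) -> tuple[pd.DataFrame, dict, dict]:
    """Dedup -> length restriction -> A-sites -> filtered density profiles."""
    restricted, _ = rp.restrict_lengths(rp.dedup(reads))
    calls = rp.map_asites(restricted, orfs)
    profiles, _ = rp.build_density_profiles(calls, orfs)
    return calls, profiles, rp.filter_orfs(profiles, min_density)


@pytest.fixture(scope="session")
def uniform_orf() -> rp.OrfRecord:
    """One 40-codon ORF with 20-nt UTRs and no special structure."""
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    cds = "".join(str(rng.choice(rp.simulate.SENSE_CODONS)) for _ in range(40))
    utr = "".join(bases[rng.integers(0, 4, 20)])
    return rp.OrfRecord("uni", utr + cds + utr, 20, 120)


@pytest.fixture(scope="session")
def stall_sim() -> tuple[rp.SyntheticTranscriptome, rp.FootprintSimulation, rp.SimulationConfig]:
    """Deeply covered simulation with one 50x short-class CGA-CGA stall per transcript."""
    cfg = rp.SimulationConfig(
        n_transcripts=12,
        codon_count_range=(300, 400),
        mean_reads_per_codon=4.0,
        class_mixture=0.5,
        stall_specs=[rp.StallSpec("CGA", "CGA", enrichment_short=50.0)],
        planted_per_spec=12,
        duplicate_fraction=0.1,
        seed=11,
    )
    tx = rp.simulate_transcriptome(cfg)
    sim = rp.simulate_footprints(tx, cfg)
    return tx, sim, cfg


def run_recovery(seed: int) -> rp.DicodonScoreTable:
    """One parameter-recovery run: three planted short-class stall pairs."""
    cfg = rp.SimulationConfig(
        n_transcripts=24,
        codon_count_range=(600, 800),
        mean_reads_per_codon=4.0,
        class_mixture=0.5,
        stall_specs=list(RECOVERY_SPECS),
        planted_per_spec=24,
        duplicate_fraction=0.05,
        seed=seed,
    )
    tx = rp.simulate_transcriptome(cfg)
    sim = rp.simulate_footprints(tx, cfg)
    _, _, retained = pipeline_core(sim.reads, tx.orfs)
    return rp.dicodon_scores(retained, tx.orfs)


@pytest.fixture(scope="session")
def recovery_tables() -> list[rp.DicodonScoreTable]:
    """Di-codon tables from the three recovery seeds."""
    return [run_recovery(seed) for seed in RECOVERY_SEEDS]


def metagene_sim(enrichment_long: float, seed: int, n: int = 30):
    """Every transcript carries a planted tract; optionally a long-class
    stall 8 codons downstream of each detected tract start."""
    cfg = rp.SimulationConfig(
        n_transcripts=n,
        codon_count_range=(150, 200),
        mean_reads_per_codon=6.0,
        n_polybasic=n,
        seed=seed,
    )
    tx = rp.simulate_transcriptome(cfg)
    tracts, _ = rp.detect_all(tx.orfs)
    if enrichment_long != 1.0:
        cfg.site_stalls = [
            rp.SiteStall(t.transcript_id, t.start_codon_index + 8, enrichment_long=enrichment_long)
            for t in tracts
        ]
    sim = rp.simulate_footprints(tx, cfg)
    _, _, retained = pipeline_core(sim.reads, tx.orfs)
    return tx, tracts, retained


@pytest.fixture(scope="session")
def planted_metagene():
    """Simulation with a 20x long-class stall planted +8 from tract starts."""
    _, tracts, retained = metagene_sim(20.0, seed=32)
    return {
        "tracts": tracts,
        "retained": retained,
        "long": rp.metagene_profile(retained, tracts, "long"),
        "short": rp.metagene_profile(retained, tracts, "short"),
    }
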