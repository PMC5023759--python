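"""End-to-end dimer scan: enumerate → refine → score → consensus."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import forcefield as ff
from .consensus import (
    ConsensusResult,
    consensus_by_frequency,
    consensus_by_values,
    normalize_scores,
)
from .poses import McSettings, enumerate_dimer_poses, refine_population
from .scoring import ScoreRecord, score_dimer
from .structure import Structure


@dataclass
class ScanResult:
    records: list[ScoreRecord]
    table: pd.DataFrame
    values: ConsensusResult
    frequency: ConsensusResult

    def top_class(self, method: str = "values") -> str:
        result = self.values if method == "values" else self.frequency
        return result.ranking[0]


def score_refined(refined, monomer: Structure,
                  config: ff.EnergyConfig = ff.DEFAULT_CONFIG,
                  probe_radius: float = 1.4, n_points: int = 92
                  ) -> list[ScoreRecord]:
    """Score a refined population, reusing the monomer atom typing.

    The protomers are rigid copies of one monomer, so the atom typing is
    computed once and shared across all poses.
    """
    params = None
    records = []
    for rp in refined:
        dimer = rp.realize()
        if params is None:
            n = len(monomer)
            pa = ff.type_atoms(dimer.atoms[:n], config)
            pb = ff.type_atoms(dimer.atoms[n:], config)
            params = (pa, pb)
        records.append(score_dimer(dimer, pose_id=rp.pose_id, config=config,
                                   probe_radius=probe_radius, n_points=n_points,
                                   params=params))
    return records


def run_dimer_scan(monomer: Structure, steps_a: int = 12, steps_b: int = 12,
                   d_contact: float = 4.0, n_outputs: int = 10,
                   mc_steps: int = 200, seed: int = 0, top_n: int = 100,
                   settings: McSettings | None = None,
                   config: ff.EnergyConfig = ff.DEFAULT_CONFIG,
                   probe_radius: float = 1.4, n_points: int = 92) -> ScanResult:
    """Full protocol on one monomer; deterministic for a fixed seed."""
    poses = enumerate_dimer_poses(monomer, steps_a, steps_b, d_contact)
    n = len(monomer)
    first = poses[0].structure
    params = (ff.type_atoms(first.atoms[:n], config),
              ff.type_atoms(first.atoms[n:], config))
    refined = refine_population(poses, n_outputs=n_outputs, mc_steps=mc_steps,
                                seed=seed, settings=settings, config=config,
                                params=params)
    records = score_refined(refined, monomer, config=config,
                            probe_radius=probe_radius, n_points=n_points)
    table = normalize_scores(records)
    values = consensus_by_values(table, top_n=top_n)
    freq = consensus_by_frequency(table, top_n=top_n)
    return ScanResult(records, table, values, freq)
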