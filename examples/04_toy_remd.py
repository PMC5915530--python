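"""Replica-exchange torsion sampling of HAIYPRH at desk scale.

A Metropolis sampler in (phi, psi) space under a chirality-aware
multi-basin potential with a geometric 300-500 K temperature ladder.
Swap acceptance statistics are reported per adjacent pair together with
the trajectory-averaged analytic Metropolis probability, so the
bookkeeping can be checked against itself.
"""

from retromimic import count_clusters, parse_sequence, self_rmsd_matrix
from retromimic.synthetic import ToySamplerConfig, remd_sample

cfg = ToySamplerConfig(
    sequence=parse_sequence("HAIYPRH"),
    n_replicas=4,
    n_steps=4000,
    swap_interval=50,
    sample_interval=40,
    seed=0,
)
result = remd_sample(cfg)
print(f"temperature ladder: {[f'{t:.0f} K' for t in cfg.temperatures]}")
for s in result.swap_stats:
    print(
        f"  pair {s.pair}: {s.accepted}/{s.attempts} swaps accepted "
        f"(empirical {s.empirical_rate:.2f}, analytic {s.mean_analytic_prob:.2f})"
    )
cold = result.ensembles[min(result.ensembles)]
n_clusters, _ = count_clusters(self_rmsd_matrix(cold), cutoff=2.0)
print(
    f"coldest replica: {cold.n_frames} frames visiting {n_clusters} "
    f"conformational clusters (2 Å single linkage)"
)
# Empirical and analytic acceptance agreeing confirms the Metropolis swap
# criterion; multiple clusters confirm the multi-basin heterogeneity the
# downstream analyses are designed to handle.
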