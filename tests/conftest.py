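import numpy as np
import pandas as pd
import pytest

from evomex import io, simulate


def build_matrix(
    deltas: dict[str, np.ndarray],
    base: np.ndarray,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    probes_per_gene: int = 1,
) -> io.ExpressionMatrix:
    """Small expression matrix with explicit per-gene group offsets.

    ``deltas`` maps group name -> per-gene offset from ``base`` (WT level).
    """
    rng = np.random.default_rng(seed)
    n = base.size
    probes = [f"g{i}_p{j}" for i in range(n) for j in range(probes_per_gene)]
    loci = [f"locus{i}" for i in range(n) for _ in range(probes_per_gene)]
    cols, rows = {}, []
    for group, delta in deltas.items():
        signal = np.repeat(base + delta, probes_per_gene)
        for r in range(1, n_replicates + 1):
            name = f"{group}_{r}"
            cols[name] = signal + rng.normal(0, noise_sd, signal.size)
            rows.append(
                {
                    "sample": name,
                    "group": group,
                    "lineage": group[4:] if group.startswith("EVO_") else "",
                }
            )
    values = pd.DataFrame(cols, index=pd.Index(probes, name="probe"))
    samples = pd.DataFrame(rows).set_index("sample")
    probe_map = pd.Series(loci, index=values.index, name="locus")
    return io.ExpressionMatrix(values=values, samples=samples, probe_map=probe_map)


@pytest.fixture
def toy_annotation() -> io.GenomeAnnotation:
    return simulate.simulate_toy_genome(seed=1)


@pytest.fixture
def expression_2000():
    """Study-condition synthetic matrix: 2000 genes, 2.0 log2 effects,
    noise 0.25, n=3 per group."""
    config = simulate.SimulationConfig(n_genes=2000, seed=42, lineages=("F1",))
    return simulate.simulate_expression(config)
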