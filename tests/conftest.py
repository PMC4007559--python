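import numpy as np
import pytest

from immunoprofiler import synthetic_tumor as st


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic tumor dataset shared across tests."""
    cfg = st.SimulationConfig(seed=3, n_genes=400, snv_count=60, error_site_count=20)
    return st.simulate_all(cfg)


@pytest.fixture(scope="session")
def small_sim_dir(small_sim, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("sim")
    paths = st.write_simulation(small_sim, outdir)
    return outdir, paths


def random_variant_records(rng: np.random.Generator, n: int):
    """Random VariantRecords with triplicate tumor/normal depths."""
    from immunoprofiler.io_formats import VariantRecord

    out = []
    used = set()
    bases = np.array(list("ACGT"))
    for i in range(n):
        while True:
            chrom = f"chr{int(rng.integers(1, 20))}"
            pos = int(rng.integers(1, 10_000_000))
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                break
        if rng.random() < 0.8:  # SNV
            ref, alt = rng.choice(bases, size=2, replace=False)
            ref, alt = str(ref), str(alt)
        else:  # anchored indel
            anchor = str(rng.choice(bases))
            tail = "".join(rng.choice(bases, size=int(rng.integers(1, 4))))
            if rng.random() < 0.5:
                ref, alt = anchor, anchor + tail
            else:
                ref, alt = anchor + tail, anchor
        depths = {}
        for sample in ("T", "N"):
            for rep in (1, 2, 3):
                d = int(rng.integers(0, 200))
                a = int(rng.integers(0, d + 1)) if d else 0
                depths[(sample, rep)] = (d - a, a)
        out.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                depths=depths,
                callers=frozenset(
                    rng.choice(["samtools", "mutect", "somaticsniper"],
                               size=int(rng.integers(1, 4)), replace=False)
                ),
                gene_id=f"g{int(rng.integers(0, 1000)):04d}" if rng.random() < 0.9 else None,
            )
        )
    return out
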