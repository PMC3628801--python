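import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from recessmap.iomodel import GenotypeDataset, Marker
from recessmap.simulate import SimConfig, simulate_cohort, simulate_variants


def make_dataset(genotype_rows, phenotypes, positions=None, chromosome="chr1",
                 marker_prefix="m"):
    """Build a GenotypeDataset from a list of per-sample genotype rows."""
    geno = np.asarray(genotype_rows, dtype=np.int8)
    n_markers = geno.shape[1]
    if positions is None:
        positions = [1000 * (i + 1) for i in range(n_markers)]
    markers = [Marker(f"{marker_prefix}{i + 1:03d}", chromosome, int(positions[i]))
               for i in range(n_markers)]
    samples = [f"s{i + 1:02d}" for i in range(geno.shape[0])]
    return GenotypeDataset(markers, samples, list(phenotypes), geno)


@pytest.fixture(scope="session")
def default_sim():
    """Default study conditions, one fixed seed, with the variant substrate."""
    cfg = SimConfig(seed=0)
    ds, truth = simulate_cohort(cfg)
    variants, panel, transcripts, coding_variants, consequences = \
        simulate_variants(cfg, truth)
    return {"cfg": cfg, "ds": ds, "truth": truth, "variants": variants,
            "panel": panel, "transcripts": transcripts,
            "coding_variants": coding_variants, "consequences": consequences}
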