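import numpy as np
import pytest

from cysmap import PeptideSpecies, composition_of, monoisotopic_mass
from cysmap.simulate import AcquisitionModel, RunEntry, random_species

# the Odorrana schmackeri peptide Odorranain-C7HSa used as the worked example
FIG2_SEQUENCE = "SLLGTVKDLLIGAGKSAAQSVLKGLSCKLSKDC"

# heterodimer of Example I: 2 chains, 8 cysteines, 4 interchain/intrachain bonds
EXAMPLE1_CHAIN1 = "LKCNTLEGRGVQATLCPPGKETCMTHSVLLNGNTNLMKGCATFSRCS"
EXAMPLE1_CHAIN2 = "SVGSNRLSESLYCCNLNLCN"


@pytest.fixture
def fig2_species():
    return PeptideSpecies(chains=(FIG2_SEQUENCE,))


@pytest.fixture
def noise_free_model():
    return AcquisitionModel(
        mz_jitter_ppm=0.0, intensity_cv=0.0, noise_peaks_per_scan=0
    )


@pytest.fixture
def run_entries():
    """Three species spanning the mass range, one charge each."""
    rng = np.random.default_rng(42)
    entries = []
    for i, (lo, hi) in enumerate([(900, 2000), (2500, 4500), (5000, 8000)]):
        sp = random_species(rng, lo, hi)
        mono = monoisotopic_mass(composition_of(sp))
        entries.append(
            RunEntry(
                species=sp,
                label=f"sp{i}",
                charges=(max(2, int(round(mono / 900.0))),),
                retention_time=60.0 * (i + 1),
            )
        )
    return entries
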