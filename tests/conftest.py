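import warnings

import pytest

from resmap import electrostatics as es
from resmap import nonpolar as npl
from resmap import structure_model as smod
from resmap import synthetic_data as syn


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="no preceding carbonyl")
        yield


@pytest.fixture(scope="session")
def helix_dimer():
    """One parameterized synthetic dimer with planted contributors + truth."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="no preceding carbonyl")
        replicate, truth = syn.make_helix_dimer(syn.SyntheticSpec(seed=1))
    return replicate, truth


@pytest.fixture(scope="session")
def helix_scan(helix_dimer):
    """Full energy scan of the session dimer (shared: the FDPB scan is the
    expensive step)."""
    replicate, truth = helix_dimer
    shell = es.interface_shell(replicate)
    elec = {r.residue_id: r for r in es.residue_scan(replicate, shell=shell)}
    mono_a, mono_b = smod.split_complex(replicate)
    nonpolar = {
        r.residue_id: r
        for r in npl.buried_area_per_residue(replicate.complex, mono_a, mono_b)
    }
    return replicate, truth, shell, elec, nonpolar


TWO_CHAIN_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.685   7.161  -4.937  1.00  0.00           C
ATOM      4  O   ALA A   1      13.412   7.500  -5.870  1.00  0.00           O
ATOM      5  CB  ALA A   1      10.542   6.195  -4.100  1.00  0.00           C
ATOM      6  N   GLY A   2      12.775   7.680  -3.713  1.00  0.00           N
ATOM      7  CA  GLY A   2      13.734   8.730  -3.396  1.00  0.00           C
ATOM      8  C   GLY A   2      13.165  10.110  -3.687  1.00  0.00           C
ATOM      9  O   GLY A   2      11.980  10.263  -3.972  1.00  0.00           O
TER
ATOM     10  N   LYS B   1       2.104   1.134   0.496  1.00  0.00           N
ATOM     11  CA  LYS B   1       2.639   1.071   1.853  1.00  0.00           C
ATOM     12  C   LYS B   1       3.685   2.161   2.063  1.00  0.00           C
ATOM     13  O   LYS B   1       4.412   2.500   1.130  1.00  0.00           O
ATOM     14  CB  LYS B   1       1.542   1.195   2.900  1.00  0.00           C
ATOM     15  NZ  LYS B   1       0.842   2.395   3.400  1.00  0.00           N
END
"""


@pytest.fixture()
def two_chain_pdb():
    return TWO_CHAIN_PDB
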