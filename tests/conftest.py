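import numpy as np
import pytest

from rxnyield.encoder import EncoderConfig, init_encoder_params

# Fifty drug-like SMILES (common drugs and fragments) used as a parse/encode
# fixture set.
DRUG_SMILES = [
    "CC(=O)Oc1ccccc1C(=O)O",  # aspirin
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",  # caffeine
    "CC(C)Cc1ccc(C(C)C(=O)O)cc1",  # ibuprofen
    "CC(=O)Nc1ccc(O)cc1",  # paracetamol
    "Clc1ccccc1-c1nnc(C2CC2)o1",
    "c1ccc2[nH]ccc2c1",  # indole
    "c1ccc2ncccc2c1",  # quinoline
    "OCC1OC(O)C(O)C(O)C1O",  # glucose
    "NC(Cc1ccccc1)C(=O)O",  # phenylalanine
    "NC(CO)C(=O)O",  # serine
    "CN1CCC[C@H]1c1cccnc1",  # nicotine
    "O=C(O)c1ccccc1O",  # salicylic acid
    "Nc1ccc(S(N)(=O)=O)cc1",  # sulfanilamide
    "CC(N)Cc1ccccc1",  # amphetamine
    "COc1cc2c(cc1OC)CCN(C)C2",
    "O=C1CCCCC1",  # cyclohexanone
    "C1CCNCC1",  # piperidine
    "C1COCCN1",  # morpholine
    "c1ccsc1",  # thiophene
    "c1ccoc1",  # furan
    "c1cc[nH]c1",  # pyrrole
    "c1ccncc1",  # pyridine
    "c1cnc2[nH]ccc2c1",
    "CC(C)(C)c1ccc(O)cc1",
    "FC(F)(F)c1ccccc1",
    "N#Cc1ccccc1",
    "O=[N+]([O-])c1ccccc1",
    "Brc1ccccc1",
    "Ic1ccccc1",
    "CSc1ccccc1",
    "CC#CC",
    "C/C=C/C",
    "CC=O",
    "CC(=O)C",
    "CCOC(C)=O",
    "CCN(CC)CC",
    "C1CC1",  # cyclopropane
    "C1CCC1",  # cyclobutane
    "C1=CC2CC1CC2",
    "OC(=O)CCC(=O)O",  # succinic acid
    "NCCCC(N)C(=O)O",
    "NC(=N)N",  # guanidine
    "O=C(N)N",  # urea
    "CN(C)C=O",  # DMF
    "CS(C)=O",  # DMSO
    "ClCCl",
    "CCCCCCCC",
    "CC(C)O",
    "OCCO",
    "Nc1ncnc2[nH]cnc12",  # adenine
]


@pytest.fixture(scope="session")
def drug_smiles():
    return list(DRUG_SMILES)


@pytest.fixture
def tiny_config():
    return EncoderConfig(hidden_size=4, depth=3, seed=11)


@pytest.fixture
def tiny_params(tiny_config):
    return init_encoder_params(tiny_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
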