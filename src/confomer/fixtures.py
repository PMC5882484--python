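"""Deterministic synthetic datasets for development and testing.

Two generators are provided, so that every component of the toolkit can be
exercised without any external download:

* :func:`make_vector_dataset` — pure sparse count vectors with a known
  linear signal and controllable heteroscedastic Gaussian noise.  Samples
  are i.i.d., hence exchangeable, so conformal validity holds by
  construction (up to binomial noise).
* :func:`make_molecule_dataset` — small molecule sets drawn from a fixed
  in-repo list of drug-like structures, with additive synthetic labels:
  each height-1..3 atom signature carries a hash-derived fragment
  contribution and the label is the contribution sum plus Gaussian noise.
  The labels are therefore linear in the signature counts (the linear SVM
  is well-specified) and are synthetic — they are NOT experimental logD.

The template list includes a handful of named reference drugs (atenolol,
sotalol, tolnaftate, amiodarone, strychnine, furosemide) as convenient
structures for gradient demos; their experimental lipophilicity plays no
role anywhere.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .chem_io import LabeledCompound, parse_smiles, standardize
from .signatures import FeatureVector, molecule_signatures


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a reproducible sparse-count regression dataset.

    noise sd per sample = noise_base + hetero_gain * (count of feature 0);
    feature 0 is drawn unconditionally (Poisson, mean ``hetero_rate``) so
    that the heteroscedastic condition actually varies across samples even
    at low density.  A small rate makes most samples "easy" (noise near
    noise_base) with a right tail of "hard" ones — the regime in which a
    per-compound error model pays off.
    """

    n: int = 1000
    p: int = 200
    density: float = 0.05
    noise_base: float = 0.3
    hetero_gain: float = 0.0
    hetero_rate: float = 1.0
    seed: int = 42
    true_weights: tuple[float, ...] | None = None

    def __post_init__(self):
        if not (0 < self.density <= 1):
            raise ValueError("density must lie in (0, 1]")
        if self.n < 1 or self.p < 2:
            raise ValueError("need n >= 1 and p >= 2")
        if self.noise_base < 0 or self.hetero_gain < 0:
            raise ValueError("noise_base >= 0 and hetero_gain >= 0 required")
        if self.hetero_rate <= 0:
            raise ValueError("hetero_rate must be positive")


def heteroscedastic_spec(n: int = 4000, seed: int = 42) -> SyntheticSpec:
    """The canonical moderately heteroscedastic study condition used by
    the validity benchmarks: sparse count features (p=200, density 0.05)
    with a linear signal and noise sd = 0.3 + 0.3 * (count of feature 0),
    feature 0 ~ Poisson(1) — the generator's default rate, with the
    heteroscedastic term sized to match the noise floor.
    """
    return SyntheticSpec(n=n, p=200, density=0.05, noise_base=0.3,
                         hetero_gain=0.3, hetero_rate=1.0, seed=seed)


def strongly_heteroscedastic_spec(n: int = 3000,
                                  seed: int = 42) -> SyntheticSpec:
    """The strongly heteroscedastic condition used by the efficiency
    benchmarks: noise sd = 0.2 + 1.0 * (count of feature 0) with feature 0
    ~ Poisson(0.5).  Most samples are easy (sd near 0.2) with a right tail
    of genuinely hard ones — the regime where a per-compound error model
    yields tighter median intervals than the constant-width measure.
    """
    return SyntheticSpec(n=n, p=200, density=0.05, noise_base=0.2,
                         hetero_gain=1.0, hetero_rate=0.5, seed=seed)


def make_vector_dataset(spec: SyntheticSpec
                        ) -> tuple[list[FeatureVector], np.ndarray]:
    """Generate (X, y) with y = w . x + N(0, sd_i), sd_i per the spec."""
    rng = np.random.default_rng(spec.seed)
    if spec.true_weights is not None:
        w = np.asarray(spec.true_weights, float)
        if w.shape != (spec.p,):
            raise ValueError("true_weights must have length p")
    else:
        w = rng.normal(0.0, 1.0, size=spec.p)

    counts = np.zeros((spec.n, spec.p), dtype=np.int64)
    counts[:, 0] = rng.poisson(spec.hetero_rate, size=spec.n)
    mask = rng.random((spec.n, spec.p - 1)) < spec.density
    counts[:, 1:] = np.where(mask, 1 + rng.poisson(1.0, (spec.n, spec.p - 1)), 0)

    sd = spec.noise_base + spec.hetero_gain * counts[:, 0]
    y = counts @ w + rng.normal(0.0, 1.0, size=spec.n) * sd

    X = [
        FeatureVector(counts={int(j): int(c) for j, c in
                              zip(np.flatnonzero(row), row[row > 0])})
        for row in counts
    ]
    return X, y


def fragment_contribution(sig, scale: float = 0.25) -> float:
    """Deterministic hash-derived contribution of one atom signature.

    The md5 digest of (height, canonical) is mapped to a uniform in
    [-0.5, 0.5) and scaled; stable across runs and platforms.
    """
    digest = hashlib.md5(
        f"{sig.height}:{sig.canonical}".encode()
    ).digest()
    u = int.from_bytes(digest[:8], "big") / 2**64
    return scale * (u - 0.5) * 2.0


def synthetic_label(mol, heights=(1, 2, 3), scale: float = 0.25) -> float:
    """Noiseless additive label: sum of per-occurrence contributions."""
    sigs = molecule_signatures(mol, heights)
    return sum(fragment_contribution(s, scale) * c for s, c in sigs.items())


def make_molecule_dataset(
    n_templates: int = 200,
    seed: int = 42,
    noise_sd: float = 0.1,
    scale: float = 0.25,
    heights=(1, 2, 3),
) -> list[LabeledCompound]:
    """Sample molecules (with replacement) from the fixed template list
    and attach additive synthetic labels plus Gaussian noise."""
    if n_templates < 1:
        raise ValueError("n_templates must be >= 1")
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(TEMPLATE_SMILES), size=n_templates)
    out = []
    for i, pick in enumerate(picks):
        smiles, name = TEMPLATE_SMILES[int(pick)]
        mol = standardize(parse_smiles(smiles))
        y = synthetic_label(mol, heights, scale)
        if noise_sd > 0:
            y += float(rng.normal(0.0, noise_sd))
        out.append(LabeledCompound(mol, y, f"{name}_{i}"))
    return out


def exemplar(name: str) -> LabeledCompound:
    """Fetch a named template (noiseless synthetic label)."""
    for smiles, nm in TEMPLATE_SMILES:
        if nm == name:
            mol = standardize(parse_smiles(smiles))
            return LabeledCompound(mol, synthetic_label(mol), name)
    raise KeyError(name)


# Fixed drug-like template structures (SMILES, name).  Structures only;
# any experimental property values of these drugs are irrelevant here.
TEMPLATE_SMILES: list[tuple[str, str]] = [
    ("CC(C)NCC(O)COc1ccc(CC(N)=O)cc1", "atenolol"),
    ("CC(C)NCC(O)c1ccc(NS(C)(=O)=O)cc1", "sotalol"),
    ("Cc1ccccc1N(C)C(=S)Oc1ccc2ccccc2c1", "tolnaftate"),
    ("CCCCc1oc2ccccc2c1C(=O)c1cc(I)c(OCCN(CC)CC)c(I)c1", "amiodarone"),
    ("O=C1CC2OCC=C3CN4CCC5(c6ccccc6N1C25)C34", "strychnine"),
    ("NS(=O)(=O)c1cc(C(=O)O)c(NCc2ccco2)cc1Cl", "furosemide"),
    ("CC(=O)Oc1ccccc1C(=O)O", "aspirin"),
    ("CC(=O)Nc1ccc(O)cc1", "paracetamol"),
    ("CC(C)Cc1ccc(C(C)C(=O)O)cc1", "ibuprofen"),
    ("COc1ccc2cc(C(C)C(=O)O)ccc2c1", "naproxen"),
    ("Cn1cnc2c1c(=O)n(C)c(=O)n2C", "caffeine"),
    ("Cn1c(=O)c2[nH]cnc2n(C)c1=O", "theophylline"),
    ("Cn1cnc2c1c(=O)[nH]c(=O)n2C", "theobromine"),
    ("CN1CCCC1c1cccnc1", "nicotine"),
    ("COCCc1ccc(OCC(O)CNC(C)C)cc1", "metoprolol"),
    ("CC(C)NCC(O)COc1cccc2ccccc12", "propranolol"),
    ("CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21", "diazepam"),
    ("OC1N=C(c2ccccc2Cl)c2cc(Cl)ccc2NC1=O", "lorazepam"),
    ("CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O", "warfarin"),
    ("CCN(CC)CC(=O)Nc1c(C)cccc1C", "lidocaine"),
    ("CCN(CC)CCOC(=O)c1ccc(N)cc1", "procaine"),
    ("CCOC(=O)c1ccc(N)cc1", "benzocaine"),
    ("O=C(O)c1ccccc1O", "salicylic-acid"),
    ("COC(=O)c1ccccc1O", "methyl-salicylate"),
    ("COc1cc(C=O)ccc1O", "vanillin"),
    ("C=CCc1ccc(O)c(OC)c1", "eugenol"),
    ("CC(C)C1CCC(C)CC1O", "menthol"),
    ("CC1(C)C2CCC1(C)C(=O)C2", "camphor"),
    ("CC1=CCC(C(=C)C)CC1", "limonene"),
    ("CNC(C)C(O)c1ccccc1", "ephedrine"),
    ("CC(N)Cc1ccccc1", "amphetamine"),
    ("NCCc1ccc(O)c(O)c1", "dopamine"),
    ("NCCc1c[nH]c2ccc(O)cc12", "serotonin"),
    ("COc1ccc2[nH]cc(CCNC(C)=O)c2c1", "melatonin"),
    ("NC(Cc1c[nH]c2ccccc12)C(=O)O", "tryptophan"),
    ("NC(Cc1ccc(O)cc1)C(=O)O", "tyrosine"),
    ("NC(Cc1ccccc1)C(=O)O", "phenylalanine"),
    ("NCCc1c[nH]cn1", "histamine"),
    ("CNCC(O)c1ccc(O)c(O)c1", "adrenaline"),
    ("CC(C)(C)NCC(O)c1ccc(O)c(CO)c1", "salbutamol"),
    ("CC(C)(C)NCC(O)c1cc(O)cc(O)c1", "terbutaline"),
    ("CN(C)CCC(c1ccc(Cl)cc1)c1ccccn1", "chlorpheniramine"),
    ("CN(C)CCOC(c1ccccc1)c1ccccc1", "diphenhydramine"),
    ("Cc1nc[nH]c1CSCCNC(=NC)NC#N", "cimetidine"),
    ("COc1ccc2[nH]c(S(=O)Cc3ncc(C)c(OC)c3C)nc2c1", "omeprazole"),
    ("Nc1ccc(S(N)(=O)=O)cc1", "sulfanilamide"),
    ("Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1", "sulfamethoxazole"),
    ("COc1cc(Cc2cnc(N)nc2N)cc(OC)c1OC", "trimethoprim"),
    ("Cc1ncc([N+](=O)[O-])n1CCO", "metronidazole"),
    ("NNC(=O)c1ccncc1", "isoniazid"),
    ("NC(=O)c1cnccn1", "pyrazinamide"),
    ("CCC(CO)NCCNC(CC)CO", "ethambutol"),
    ("CCN(CC)CCCC(C)Nc1ccnc2cc(Cl)ccc12", "chloroquine"),
    ("COc1ccc2nccc(C(O)C3CC4CCN3CC4C=C)c2c1", "quinine"),
    ("COc1cc(NC(C)CCCN)c2ncccc2c1", "primaquine"),
    ("Nc1ccc(S(=O)(=O)c2ccc(N)cc2)cc1", "dapsone"),
    ("CCC1(c2ccccc2)C(=O)NC(=O)NC1=O", "phenobarbital"),
    ("O=C1NC(=O)C(c2ccccc2)(c2ccccc2)N1", "phenytoin"),
    ("NC(=O)N1c2ccccc2C=Cc2ccccc21", "carbamazepine"),
    ("CCCC(CCC)C(=O)O", "valproic-acid"),
    ("NCC1(CC(=O)O)CCCCC1", "gabapentin"),
    ("NCC(CC(=O)O)c1ccc(Cl)cc1", "baclofen"),
    ("CNC1(c2ccccc2Cl)CCCCC1=O", "ketamine"),
    ("CN(C)CC1CCCCC1(O)c1cccc(OC)c1", "tramadol"),
    ("CCC(=O)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1", "fentanyl"),
    ("CCOC(=O)C1(c2ccccc2)CCN(C)CC1", "pethidine"),
    ("COC(=O)C1C(OC(=O)c2ccccc2)CC2CCC1N2C", "cocaine"),
    ("CN1C2CCC1CC(OC(=O)C(CO)c1ccccc1)C2", "atropine"),
    ("O=C(CCCN1CCC(O)(c2ccc(Cl)cc2)CC1)c1ccc(F)cc1", "haloperidol"),
    ("CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21", "chlorpromazine"),
    ("CC(CN1c2ccccc2Sc2ccccc21)N(C)C", "promethazine"),
    ("CN(C)CCCN1c2ccccc2CCc2ccccc21", "imipramine"),
    ("CN(C)CCC=C1c2ccccc2CCc2ccccc21", "amitriptyline"),
    ("CNCCC(Oc1ccc(C(F)(F)F)cc1)c1ccccc1", "fluoxetine"),
    ("CNC1CCC(c2ccc(Cl)c(Cl)c2)c2ccccc21", "sertraline"),
    ("CN(C)CCCC1(c2ccc(F)cc2)OCc2cc(C#N)ccc21", "citalopram"),
    ("CN(C)CC(c1ccc(OC)cc1)C1(O)CCCCC1", "venlafaxine"),
    ("CC(NC(C)(C)C)C(=O)c1cccc(Cl)c1", "bupropion"),
    ("O=C1CC2(CCCC2)CC(=O)N1CCCCN1CCN(c2ncccn2)CC1", "buspirone"),
    ("Cc1ccc(-c2nc3ccc(C)cn3c2CC(=O)N(C)C)cc1", "zolpidem"),
    ("COC(=O)C1=C(C)NC(C)=C(C(=O)OC)C1c1ccccc1[N+](=O)[O-]", "nifedipine"),
    ("CCOC(=O)C1=C(COCCN)NC(C)=C(C(=O)OC)C1c1ccccc1Cl", "amlodipine"),
    ("COc1ccc(CCN(C)CCCC(C#N)(C(C)C)c2ccc(OC)c(OC)c2)cc1OC", "verapamil"),
    ("CC(=O)OC1C(c2ccc(OC)cc2)Sc2ccccc2N(CCN(C)C)C1=O", "diltiazem"),
    ("CC(CS)C(=O)N1CCCC1C(=O)O", "captopril"),
    ("CCOC(=O)C(CCc1ccccc1)NC(C)C(=O)N1CCCC1C(=O)O", "enalapril"),
    ("NCCCCC(NC(CCc1ccccc1)C(=O)O)C(=O)N1CCCC1C(=O)O", "lisinopril"),
    ("CCCCc1nc(Cl)c(CO)n1Cc1ccc(-c2ccccc2-c2nnn[nH]2)cc1", "losartan"),
    ("CCCCC(=O)N(Cc1ccc(-c2ccccc2-c2nnn[nH]2)cc1)C(C(C)C)C(=O)O",
     "valsartan"),
    ("NS(=O)(=O)c1cc2c(cc1Cl)NCNS2(=O)=O", "hydrochlorothiazide"),
    ("CCC(C)(C)C(=O)OC1CC(C)C=C2C=CC(C)C(CCC3CC(O)CC(=O)O3)C21",
     "simvastatin"),
    ("CC(C)c1c(C(=O)Nc2ccccc2)c(-c2ccccc2)c(-c2ccc(F)cc2)n1CCC(O)CC(O)CC(=O)O",
     "atorvastatin"),
    ("Cc1ccc(C)c(OCCCC(C)(C)C(=O)O)c1", "gemfibrozil"),
    ("CC(C)OC(=O)C(C)(C)Oc1ccc(C(=O)c2ccc(Cl)cc2)cc1", "fenofibrate"),
    ("CN(C)C(=N)NC(=N)N", "metformin"),
    ("COc1ccc(Cl)cc1C(=O)NCCc1ccc(S(=O)(=O)NC(=O)NC2CCCCC2)cc1",
     "glibenclamide"),
    ("CCc1ccc(CCOc2ccc(CC3SC(=O)NC3=O)cc2)nc1", "pioglitazone"),
    ("CN(CCOc1ccc(CC2SC(=O)NC2=O)cc1)c1ccccn1", "rosiglitazone"),
    ("COc1cc2c(c(OC)c1OC)-c1ccc(OC)c(=O)cc1C(NC(C)=O)CC2", "colchicine"),
    ("CCCN(CCC)S(=O)(=O)c1ccc(C(=O)O)cc1", "probenecid"),
    ("COc1ccc2c(c1)c(CC(=O)O)c(C)n2C(=O)c1ccc(Cl)cc1", "indomethacin"),
    ("O=C(O)Cc1ccccc1Nc1c(Cl)cccc1Cl", "diclofenac"),
    ("CC(C(=O)O)c1cccc(C(=O)c2ccccc2)c1", "ketoprofen"),
    ("CN1C(C(=O)Nc2ccccn2)=C(O)c2ccccc2S1(=O)=O", "piroxicam"),
    ("Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1", "celecoxib"),
    ("CN1C(C(=O)Nc2ncc(C)s2)=C(O)c2ccccc2S1(=O)=O", "meloxicam"),
    ("Cc1cccc(Nc2ccccc2C(=O)O)c1C", "mefenamic-acid"),
    ("Fc1ccc(C2CCNCC2COc2ccc3OCOc3c2)cc1", "paroxetine"),
    ("O=C(O)COCCN1CCN(C(c2ccccc2)c2ccc(Cl)cc2)CC1", "cetirizine"),
    ("CCOC(=O)N1CCC(=C2c3ccc(Cl)cc3CCc3cccnc32)CC1", "loratadine"),
    ("CC(C)(C(=O)O)c1ccc(C(O)CCCN2CCC(C(O)(c3ccccc3)c3ccccc3)CC2)cc1",
     "fexofenadine"),
    ("OCc1cc(C(O)CNCCCCCCOCCCCc2ccccc2)ccc1O", "salmeterol"),
    ("Nc1nc2c(c(=O)[nH]1)ncn2COCCO", "acyclovir"),
    ("Cc1cn(C2CC(N=[N+]=[N-])C(CO)O2)c(=O)[nH]c1=O", "zidovudine"),
    ("Nc1ccn(C2CSC(CO)O2)c(=O)n1", "lamivudine"),
    ("CCOC(=O)C1=CC(OC(CC)CC)C(NC(C)=O)C(N)C1", "oseltamivir"),
    ("OC(Cn1cncn1)(Cn1cncn1)c1ccc(F)cc1F", "fluconazole"),
    ("Clc1ccc(C(Cn2ccnc2)OCc2ccc(Cl)cc2Cl)c(Cl)c1", "miconazole"),
    ("CC(C)(C)C#CC=CCN(C)Cc1cccc2ccccc12", "terbinafine"),
    ("COC1=CC(=O)CC(C)C11Oc2c(Cl)c(OC)cc(OC)c2C1=O", "griseofulvin"),
    ("CC1(C)SC2C(NC(=O)C(N)c3ccc(O)cc3)C(=O)N2C1C(=O)O", "amoxicillin"),
    ("CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O", "penicillin-g"),
    ("CC1=C(C(=O)O)N2C(=O)C(NC(=O)C(N)c3ccccc3)C2SC1", "cephalexin"),
    ("O=C(O)c1cn(C2CC2)c2cc(N3CCNCC3)c(F)cc2c1=O", "ciprofloxacin"),
    ("CCn1cc(C(=O)O)c(=O)c2cc(F)c(N3CCNCC3)cc21", "norfloxacin"),
    ("O=[N+]([O-])c1ccc(C(O)C(CO)NC(=O)C(Cl)Cl)cc1", "chloramphenicol"),
    ("CC(=O)NCC1CN(c2ccc(N3CCOCC3)c(F)c2)C(=O)O1", "linezolid"),
    ("O=C1CN(N=Cc2ccc([N+](=O)[O-])o2)C(=O)N1", "nitrofurantoin"),
    ("CN(Cc1cnc2nc(N)nc(N)c2n1)c1ccc(C(=O)NC(CCC(=O)O)C(=O)O)cc1",
     "methotrexate"),
    ("O=c1[nH]cc(F)c(=O)[nH]1", "fluorouracil"),
    ("Nc1ccn(C2OC(CO)C(O)C2O)c(=O)n1", "cytarabine"),
    ("Nc1ccn(C2OC(CO)C(O)C2(F)F)c(=O)n1", "gemcitabine"),
    ("Cc1ccc(NC(=O)c2ccc(CN3CCN(C)CC3)cc2)cc1Nc1nccc(-c2cccnc2)n1",
     "imatinib"),
    ("COc1cc2ncnc(Nc3ccc(F)c(Cl)c3)c2cc1OCCCN1CCOCC1", "gefitinib"),
    ("C#Cc1cccc(Nc2ncnc3cc(OCCOC)c(OCCOC)cc23)c1", "erlotinib"),
    ("CNC(=O)c1cc(Oc2ccc(NC(=O)Nc3ccc(Cl)c(C(F)(F)F)c3)cc2)ccn1",
     "sorafenib"),
    ("CCC(=C(c1ccccc1)c1ccc(OCCN(C)C)cc1)c1ccccc1", "tamoxifen"),
    ("N#Cc1ccc(C(c2ccc(C#N)cc2)n2cncn2)cc1", "letrozole"),
    ("CC(C)(C#N)c1cc(Cn2cncn2)cc(C(C)(C)C#N)c1", "anastrozole"),
    ("CC(O)(CS(=O)(=O)c1ccc(F)cc1)C(=O)Nc1ccc(C#N)c(C(F)(F)F)c1",
     "bicalutamide"),
    ("CC(C)C(=O)Nc1ccc([N+](=O)[O-])c(C(F)(F)F)c1", "flutamide"),
    ("CC12CCC3C(CCC4=CC(=O)CCC43C)C1CCC2O", "testosterone"),
    ("CC12CCC3c4ccc(O)cc4CCC3C1CCC2O", "estradiol"),
    ("CC(=O)C1CCC2C1(C)CCC1C2CCC2=CC(=O)CCC12C", "progesterone"),
    ("OCC(=O)C1(O)CCC2C1(C)CC(O)C1C2CCC2=CC(=O)CCC12C", "hydrocortisone"),
    ("CC(C)CCCC(C)C1CCC2C1(C)CCC1C2CC=C2CC(O)CCC12C", "cholesterol"),
    ("c1ccncc1", "pyridine"),
    ("c1cncnc1", "pyrimidine"),
    ("c1cnccn1", "pyrazine"),
    ("c1cc[nH]c1", "pyrrole"),
    ("c1c[nH]cn1", "imidazole"),
    ("c1ccoc1", "furan"),
    ("c1ccsc1", "thiophene"),
    ("c1ccc2[nH]ccc2c1", "indole"),
    ("c1ccc2ncccc2c1", "quinoline"),
    ("c1ccc2cnccc2c1", "isoquinoline"),
    ("c1ccc2[nH]cnc2c1", "benzimidazole"),
    ("c1ccc2scnc2c1", "benzothiazole"),
    ("c1ccc2occc2c1", "benzofuran"),
    ("c1ccc2ocnc2c1", "benzoxazole"),
    ("c1ncc2[nH]cnc2n1", "purine"),
    ("c1ccc2c(c1)[nH]c1ccccc12", "carbazole"),
    ("c1ccc2nc3ccccc3cc2c1", "acridine"),
    ("C1c2ccccc2-c2ccccc21", "fluorene"),
    ("c1ccc2cc3ccccc3cc2c1", "anthracene"),
    ("c1ccc2ccc3ccccc3c2c1", "phenanthrene"),
    ("c1ccc2ccccc2c1", "naphthalene"),
    ("c1ccc(-c2ccccc2)cc1", "biphenyl"),
    ("O=C(c1ccccc1)c1ccccc1", "benzophenone"),
    ("C(c1ccccc1)c1ccccc1", "diphenylmethane"),
    ("Cc1ccccc1", "toluene"),
    ("Cc1ccccc1C", "o-xylene"),
    ("Cc1cc(C)cc(C)c1", "mesitylene"),
    ("Oc1ccccc1", "phenol"),
    ("Oc1ccccc1O", "catechol"),
    ("Oc1cccc(O)c1", "resorcinol"),
    ("Oc1ccc(O)cc1", "hydroquinone"),
    ("Cc1ccc(O)cc1", "p-cresol"),
    ("Nc1ccccc1", "aniline"),
    ("COc1ccccc1", "anisole"),
    ("O=[N+]([O-])c1ccccc1", "nitrobenzene"),
    ("NC(=O)c1ccccc1", "benzamide"),
    ("CC(=O)c1ccccc1", "acetophenone"),
    ("C=Cc1ccccc1", "styrene"),
    ("O=Cc1ccccc1", "benzaldehyde"),
    ("OC(=O)c1ccccc1", "benzoic-acid"),
    ("N#Cc1ccccc1", "benzonitrile"),
    ("OCc1ccccc1", "benzyl-alcohol"),
    ("NCCc1ccccc1", "phenethylamine"),
    ("O=C(O)C=Cc1ccccc1", "cinnamic-acid"),
    ("O=c1ccc2ccccc2o1", "coumarin"),
    ("O=c1ccoc2ccccc12", "chromone"),
    ("Clc1ccccc1", "chlorobenzene"),
    ("Brc1ccccc1", "bromobenzene"),
    ("Fc1ccccc1", "fluorobenzene"),
    ("C1CCNCC1", "piperidine"),
    ("C1CNCCN1", "piperazine"),
    ("C1COCCN1", "morpholine"),
    ("C1CCOC1", "tetrahydrofuran"),
    ("C1COCCO1", "dioxane"),
    ("C1CCCCC1", "cyclohexane"),
    ("C1C2CC3CC1CC(C2)C3", "adamantane"),
    ("NCC(=O)O", "glycine"),
    ("CC(N)C(=O)O", "alanine"),
    ("CC(C)CC(N)C(=O)O", "leucine"),
    ("CC(C)C(N)C(=O)O", "valine"),
    ("OCC(N)C(=O)O", "serine"),
    ("NCCCCC(N)C(=O)O", "lysine"),
    ("NC(CCC(=O)O)C(=O)O", "glutamic-acid"),
    ("NC(CC(=O)O)C(=O)O", "aspartic-acid"),
    ("O=C(O)C1CCCN1", "proline"),
    ("OCC1OC(O)C(O)C(O)C1O", "glucose"),
    ("OC(=O)CC(O)(CC(=O)O)C(=O)O", "citric-acid"),
    ("NC(N)=O", "urea"),
    ("OCC(O)CO", "glycerol"),
    ("CC(O)C(=O)O", "lactic-acid"),
    ("O=C(O)CCC(=O)O", "succinic-acid"),
    ("O=C(O)C=CC(=O)O", "fumaric-acid"),
    ("CCCCCCCCO", "octanol"),
    ("CCO", "ethanol"),
    ("CC(C)=O", "acetone"),
    ("CS(C)=O", "dmso"),
]
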