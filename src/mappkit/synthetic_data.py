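"""Synthetic MAPPs donor panels with full ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: nested sets of peptides with ragged N/C termini around planted
9-mer binding cores, donor-specific presentation (Bernoulli per
donor x core), a peptide length distribution targeting a median of 16
residues, a large self-peptide background drawn from a synthetic
proteome, reversed-sequence decoys, charge states 2-7 with log-normal
XCorr score distributions for true vs false matches, Met-oxidation and
N/Q-deamidation injection with localized/unlocalized status, and
per-replicate peptide dropout.

Everything is deterministic given the seed, and the generation order is
fixed so that the therapeutic peptide inventory does not depend on the
background size: chains, cores, proteome, presentation and ladders are
drawn before any per-sample background.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .clustering import Cluster, interval_overlap
from .errors import ConfigError
from .psm_io import Modification, PSMRecord, write_psm_table
from .sequence_model import (
    CdrInterval,
    TherapeuticChain,
    TherapeuticMolecule,
    write_therapeutic,
)

ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

CORE_LENGTH = 9


@dataclass(frozen=True)
class PlantedCore:
    core_id: str
    chain_id: str
    start: int
    end: int

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic donor panel.  All draws derive from ``seed``."""

    seed: int = 0
    molecule_name: str = "mAb-SIM"
    n_donors: int = 7
    n_replicates_per_donor: int = 1
    analysts: tuple[str, ...] = ("A", "B")
    days: tuple[str, ...] = ("1", "2", "3")

    # therapeutic construct
    hc_length: int = 220
    lc_length: int = 110
    hc_cdrs: tuple[tuple[str, int, int], ...] = (
        ("HC CDR1", 31, 35),
        ("HC CDR2", 50, 66),
        ("HC CDR3", 99, 110),
    )
    lc_cdrs: tuple[tuple[str, int, int], ...] = (
        ("LC CDR1", 24, 34),
        ("LC CDR2", 50, 56),
        ("LC CDR3", 89, 97),
    )

    # planted binding cores
    n_cores_hc: int = 2
    n_cores_lc: int = 1
    core_positions: tuple[tuple[str, int], ...] | None = None  # (chain_id, start) overrides
    core_min_separation: int = 50  # start-to-start, same chain
    core_margin: int = 20  # distance kept from chain ends

    # presentation / ladder structure
    donor_presentation_prob: float = 0.7
    presentation_probs: Mapping[str, float] | None = None  # per-core_id override
    ladder_mean: float = 5.0  # Poisson, min 1 peptide per presented core
    ext_offset: int = 2  # minimum ragged extension per terminus
    ext_geom_p: float = 0.35
    min_length: int = 11
    max_length: int = 25
    replicate_dropout_prob: float = 0.02

    # background & decoys
    n_background_proteins: int = 150
    background_protein_length: int = 400
    background_peptides: int = 12000
    decoy_fraction: float = 0.5  # fraction of the raw PSM list that is decoy
    false_target_fraction: float = 0.05  # background rows that are wrong matches

    # scores and charges
    charge_probs: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.45, 3: 0.35, 4: 0.12, 5: 0.05, 6: 0.02, 7: 0.01}
    )
    true_xcorr_logmu: Mapping[int, float] = field(
        default_factory=lambda: {2: 1.2238, 3: 1.4351, 4: 1.5686}  # ln 3.4 / 4.2 / 4.8
    )
    true_xcorr_logsigma: float = 0.2
    false_xcorr_logmu: float = -0.105  # ln 0.9
    false_xcorr_logsigma: float = 0.25

    # modifications
    metox_prob: float = 0.3
    deamidation_prob: float = 0.15
    unlocalized_fraction: float = 0.3

    def __post_init__(self):
        probs = {
            "donor_presentation_prob": self.donor_presentation_prob,
            "decoy_fraction": self.decoy_fraction,
            "false_target_fraction": self.false_target_fraction,
            "replicate_dropout_prob": self.replicate_dropout_prob,
            "metox_prob": self.metox_prob,
            "deamidation_prob": self.deamidation_prob,
            "unlocalized_fraction": self.unlocalized_fraction,
            "ext_geom_p": self.ext_geom_p,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {p}")
        if not (0.0 < self.ext_geom_p):
            raise ConfigError("ext_geom_p must be positive")
        if self.decoy_fraction >= 1.0:
            raise ConfigError("decoy_fraction must be < 1")
        if self.presentation_probs:
            for cid, p in self.presentation_probs.items():
                if not (0.0 <= p <= 1.0):
                    raise ConfigError(f"presentation prob for {cid} outside [0, 1]")
        if self.n_donors < 1:
            raise ConfigError("n_donors must be >= 1")
        if self.n_replicates_per_donor < 1:
            raise ConfigError("n_replicates_per_donor must be >= 1")
        if self.core_min_separation <= 25:
            raise ConfigError("planted cores must be separated by > 25 residues")
        if not (CORE_LENGTH <= self.min_length <= self.max_length):
            raise ConfigError("need core length <= min_length <= max_length")
        if self.core_margin < self.max_length - CORE_LENGTH:
            raise ConfigError(
                "core_margin must cover the maximum terminal extension "
                f"({self.max_length - CORE_LENGTH})"
            )
        if abs(sum(self.charge_probs.values()) - 1.0) > 1e-9:
            raise ConfigError("charge_probs must sum to 1")
        if set(self.charge_probs) - set(range(2, 8)):
            raise ConfigError("charge_probs keys must lie in 2-7")
        if self.ladder_mean <= 0:
            raise ConfigError("ladder_mean must be positive")


@dataclass
class PanelTruth:
    """Ground truth emitted alongside a simulated panel."""

    planted_cores: list[PlantedCore]
    presentation: dict[tuple[str, str], bool]  # (donor_id, core_id) -> presented
    #: every generated ladder peptide (before replicate dropout):
    #: (donor_id, core_id, chain_id, start, end)
    ladder_peptides: list[tuple[str, str, str, int, int]]
    #: per sample, aligned with record order: (is_true_match, core_id or None)
    row_labels: dict[str, list[tuple[bool, str | None]]]
    #: injected therapeutic modifications:
    #: (donor_id, core_id, chain_id, pep_start, pep_end, kind, chain_pos, localized)
    mod_events: list[tuple[str, str, str, int, int, str, int, bool]]
    _label_by_id: dict[int, tuple[bool, str | None]] = field(default_factory=dict, repr=False)

    def label_of(self, record: PSMRecord) -> tuple[bool, str | None]:
        """(is_true_match, core_id) for a record of this panel."""
        return self._label_by_id[id(record)]

    def presented_pairs(self) -> list[tuple[str, str]]:
        return [pair for pair, present in sorted(self.presentation.items()) if present]


@dataclass
class SimulatedPanel:
    config: SimulationConfig
    molecule: TherapeuticMolecule
    background_proteome: dict[str, str]
    donors: list[str]
    samples: dict[str, list[PSMRecord]]  # sample_id -> records, fixed order
    sample_donor: dict[str, str]
    truth: PanelTruth

    def all_records(self) -> list[PSMRecord]:
        out: list[PSMRecord] = []
        for sid in sorted(self.samples):
            out.extend(self.samples[sid])
        return out

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA/regions/background/PSM/truth files (text formats only)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["therapeutic_fasta"] = outdir / "therapeutic.fasta"
        paths["regions"] = outdir / "regions.tsv"
        write_therapeutic(self.molecule, paths["therapeutic_fasta"], paths["regions"])

        paths["background_fasta"] = outdir / "background.fasta"
        with open(paths["background_fasta"], "w") as fh:
            for name in sorted(self.background_proteome):
                fh.write(f">{name}\n{self.background_proteome[name]}\n")

        psm_dir = outdir / "psm"
        psm_dir.mkdir(exist_ok=True)
        for sid in sorted(self.samples):
            path = psm_dir / f"{sid}.tsv"
            write_psm_table(self.samples[sid], path)
            paths[f"psm:{sid}"] = path

        truth_dir = outdir / "truth"
        truth_dir.mkdir(exist_ok=True)
        paths["truth_cores"] = truth_dir / "planted_cores.tsv"
        with open(paths["truth_cores"], "w") as fh:
            fh.write("core_id\tchain_id\tstart\tend\n")
            for c in self.truth.planted_cores:
                fh.write(f"{c.core_id}\t{c.chain_id}\t{c.start}\t{c.end}\n")
        paths["truth_presentation"] = truth_dir / "presentation.tsv"
        with open(paths["truth_presentation"], "w") as fh:
            fh.write("donor_id\tcore_id\tpresented\n")
            for (donor, core_id), present in sorted(self.truth.presentation.items()):
                fh.write(f"{donor}\t{core_id}\t{'true' if present else 'false'}\n")
        paths["truth_rows"] = truth_dir / "psm_labels.tsv"
        with open(paths["truth_rows"], "w") as fh:
            fh.write("sample_id\trow_index\tis_true\tcore_id\n")
            for sid in sorted(self.truth.row_labels):
                for i, (is_true, core_id) in enumerate(self.truth.row_labels[sid]):
                    fh.write(
                        f"{sid}\t{i}\t{'true' if is_true else 'false'}\t{core_id or ''}\n"
                    )
        paths["truth_ladders"] = truth_dir / "ladder_peptides.tsv"
        with open(paths["truth_ladders"], "w") as fh:
            fh.write("donor_id\tcore_id\tchain_id\tstart\tend\n")
            for donor, core_id, chain_id, start, end in self.truth.ladder_peptides:
                fh.write(f"{donor}\t{core_id}\t{chain_id}\t{start}\t{end}\n")
        paths["truth_mods"] = truth_dir / "mod_events.tsv"
        with open(paths["truth_mods"], "w") as fh:
            fh.write(
                "donor_id\tcore_id\tchain_id\tpep_start\tpep_end\tkind\tchain_pos\tlocalized\n"
            )
            for ev in self.truth.mod_events:
                donor, core_id, chain_id, ps, pe, kind, pos, localized = ev
                fh.write(
                    f"{donor}\t{core_id}\t{chain_id}\t{ps}\t{pe}\t{kind}\t{pos}\t"
                    f"{'true' if localized else 'false'}\n"
                )
        return paths


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(ALPHABET[rng.integers(0, len(ALPHABET), size=length)])


def _place_cores(
    rng: np.random.Generator, chain_len: int, n: int, margin: int, min_sep: int
) -> list[int]:
    if n == 0:
        return []
    lo = margin + 1
    hi = chain_len - margin - CORE_LENGTH + 1
    if hi < lo:
        raise ConfigError(f"chain of length {chain_len} too short for planted cores")
    for _ in range(10000):
        starts = np.sort(rng.integers(lo, hi + 1, size=n))
        if n == 1 or np.all(np.diff(starts) >= min_sep):
            return [int(s) for s in starts]
    raise ConfigError(
        f"cannot place {n} cores with separation {min_sep} on a chain of length {chain_len}"
    )


def _sample_lengths(
    rng: np.random.Generator, cfg: SimulationConfig, n: int
) -> np.ndarray:
    """Total peptide lengths: core + two ragged extensions, truncated to range."""
    out = np.empty(n, dtype=np.int64)
    remaining = np.arange(n)
    while remaining.size:
        n_ext = cfg.ext_offset + rng.geometric(cfg.ext_geom_p, size=remaining.size) - 1
        c_ext = cfg.ext_offset + rng.geometric(cfg.ext_geom_p, size=remaining.size) - 1
        lengths = CORE_LENGTH + n_ext + c_ext
        ok = (lengths >= cfg.min_length) & (lengths <= cfg.max_length)
        out[remaining[ok]] = lengths[ok]
        remaining = remaining[~ok]
    return out


def _sample_extensions(
    rng: np.random.Generator, cfg: SimulationConfig, max_n: int, max_c: int
) -> tuple[int, int]:
    """One (n_ext, c_ext) pair subject to length and chain-boundary caps."""
    while True:
        n_ext = int(cfg.ext_offset + rng.geometric(cfg.ext_geom_p) - 1)
        c_ext = int(cfg.ext_offset + rng.geometric(cfg.ext_geom_p) - 1)
        length = CORE_LENGTH + n_ext + c_ext
        if (
            cfg.min_length <= length <= cfg.max_length
            and n_ext <= max_n
            and c_ext <= max_c
        ):
            return n_ext, c_ext


def _inject_mods(
    rng: np.random.Generator, cfg: SimulationConfig, peptide: str
) -> list[Modification]:
    mods: list[Modification] = []
    for i, res in enumerate(peptide, start=1):
        if res == "M":
            if rng.random() < cfg.metox_prob:
                mods.append(Modification("MetOx", "M", i))
        elif res in "NQ":
            if rng.random() < cfg.deamidation_prob:
                pos = None if rng.random() < cfg.unlocalized_fraction else i
                mods.append(Modification("Deamidation", res, pos))
    return mods


def _background_mods(
    rng: np.random.Generator, cfg: SimulationConfig, peptides: list[str]
) -> list[list[Modification]]:
    """Vectorised modification injection for the (large) background set."""
    n = len(peptides)
    m_counts = np.fromiter((p.count("M") for p in peptides), dtype=np.int64, count=n)
    nq_counts = np.fromiter(
        (p.count("N") + p.count("Q") for p in peptides), dtype=np.int64, count=n
    )
    n_ox = rng.binomial(m_counts, cfg.metox_prob)
    n_deam = rng.binomial(nq_counts, cfg.deamidation_prob)
    mods_per_peptide: list[list[Modification]] = [[] for _ in range(n)]
    hot = np.flatnonzero((n_ox > 0) | (n_deam > 0))
    for idx in hot:
        pep = peptides[idx]
        mods: list[Modification] = []
        if n_ox[idx]:
            m_pos = [i + 1 for i, r in enumerate(pep) if r == "M"]
            for i in rng.choice(len(m_pos), size=n_ox[idx], replace=False):
                mods.append(Modification("MetOx", "M", m_pos[i]))
        if n_deam[idx]:
            nq_pos = [i + 1 for i, r in enumerate(pep) if r in "NQ"]
            for i in rng.choice(len(nq_pos), size=n_deam[idx], replace=False):
                pos = int(nq_pos[i])
                if rng.random() < cfg.unlocalized_fraction:
                    mods.append(Modification("Deamidation", pep[pos - 1], None))
                else:
                    mods.append(Modification("Deamidation", pep[pos - 1], pos))
        mods_per_peptide[idx] = mods
    return mods_per_peptide


def simulate_panel(config: SimulationConfig, seed: int | None = None) -> SimulatedPanel:
    """Generate one synthetic donor panel; deterministic given the seed."""
    cfg = config if seed is None else replace(config, seed=seed)
    rng = np.random.default_rng(cfg.seed)

    # 1. therapeutic construct
    hc = TherapeuticChain(
        "HC",
        _random_sequence(rng, cfg.hc_length),
        [CdrInterval("HC", n, s, e) for n, s, e in cfg.hc_cdrs],
    )
    lc = TherapeuticChain(
        "LC",
        _random_sequence(rng, cfg.lc_length),
        [CdrInterval("LC", n, s, e) for n, s, e in cfg.lc_cdrs],
    )
    molecule = TherapeuticMolecule(cfg.molecule_name, hc, lc)

    # 2. planted cores
    cores: list[PlantedCore] = []
    if cfg.core_positions is not None:
        counters = {"HC": 0, "LC": 0}
        for chain_id, start in cfg.core_positions:
            counters[chain_id] += 1
            cores.append(
                PlantedCore(
                    f"{chain_id}{counters[chain_id]}", chain_id, start, start + CORE_LENGTH - 1
                )
            )
        for c in cores:
            chain_len = len(molecule.chain(c.chain_id))
            if not (cfg.core_margin < c.start and c.end <= chain_len - cfg.core_margin):
                raise ConfigError(f"core {c.core_id} too close to a chain end")
        by_chain: dict[str, list[PlantedCore]] = {}
        for c in cores:
            by_chain.setdefault(c.chain_id, []).append(c)
        for chain_cores in by_chain.values():
            starts = sorted(c.start for c in chain_cores)
            if any(b - a < cfg.core_min_separation for a, b in zip(starts, starts[1:])):
                raise ConfigError("planted cores closer than core_min_separation")
    else:
        for chain_id, n in (("HC", cfg.n_cores_hc), ("LC", cfg.n_cores_lc)):
            chain_len = len(molecule.chain(chain_id))
            starts = _place_cores(
                rng, chain_len, n, cfg.core_margin, cfg.core_min_separation
            )
            for i, s in enumerate(starts, start=1):
                cores.append(PlantedCore(f"{chain_id}{i}", chain_id, s, s + CORE_LENGTH - 1))

    # 3. background proteome (fixed draw count: independent of background_peptides)
    background_proteome = {
        f"SELFPROT{i:04d}": _random_sequence(rng, cfg.background_protein_length)
        for i in range(cfg.n_background_proteins)
    }

    donors = [f"D{i:02d}" for i in range(1, cfg.n_donors + 1)]

    # 4. presentation matrix
    presentation: dict[tuple[str, str], bool] = {}
    for donor in donors:
        for core in cores:
            p = cfg.donor_presentation_prob
            if cfg.presentation_probs and core.core_id in cfg.presentation_probs:
                p = cfg.presentation_probs[core.core_id]
            presentation[(donor, core.core_id)] = bool(rng.random() < p)

    # 5. nested-set ladders (shared across a donor's replicates)
    ladders: dict[str, list[tuple[PlantedCore, int, int, list[Modification]]]] = {
        donor: [] for donor in donors
    }
    ladder_peptides: list[tuple[str, str, str, int, int]] = []
    mod_events: list[tuple[str, str, str, int, int, str, int, bool]] = []
    for donor in donors:
        for core in cores:
            if not presentation[(donor, core.core_id)]:
                continue
            chain = molecule.chain(core.chain_id)
            size = max(1, int(rng.poisson(cfg.ladder_mean)))
            for _ in range(size):
                n_ext, c_ext = _sample_extensions(
                    rng, cfg, max_n=core.start - 1, max_c=len(chain) - core.end
                )
                start, end = core.start - n_ext, core.end + c_ext
                peptide = chain.region(start, end)
                mods = _inject_mods(rng, cfg, peptide)
                ladders[donor].append((core, start, end, mods))
                ladder_peptides.append((donor, core.core_id, core.chain_id, start, end))
                for m in mods:
                    true_site = m.position
                    if true_site is None:
                        # the injected site is unknowable from the record; truth
                        # keeps the residue kind only (chain_pos 0 sentinel)
                        chain_pos = 0
                    else:
                        chain_pos = start + true_site - 1
                    mod_events.append(
                        (
                            donor,
                            core.core_id,
                            core.chain_id,
                            start,
                            end,
                            m.kind,
                            chain_pos,
                            m.position is not None,
                        )
                    )

    # 6. per-sample assembly: therapeutic (minus dropout) + background + decoys
    chain_seqs = [hc.sequence, lc.sequence]
    protein_names = sorted(background_proteome)
    protein_seqs = [background_proteome[n] for n in protein_names]
    charges_domain = np.array(sorted(cfg.charge_probs), dtype=np.int64)
    charge_p = np.array([cfg.charge_probs[c] for c in charges_domain])

    samples: dict[str, list[PSMRecord]] = {}
    sample_donor: dict[str, str] = {}
    row_labels: dict[str, list[tuple[bool, str | None]]] = {}
    label_by_id: dict[int, tuple[bool, str | None]] = {}

    for donor in donors:
        for rep in range(1, cfg.n_replicates_per_donor + 1):
            sample_id = f"{donor}_r{rep}"
            day = cfg.days[(rep - 1) % len(cfg.days)]
            analyst = cfg.analysts[(rep - 1) % len(cfg.analysts)]
            sample_donor[sample_id] = donor

            rows: list[tuple[str, list[Modification], list[str], bool, bool, str | None]] = []
            # (peptide, mods, proteins, is_decoy, is_true, core_id)
            for core, start, end, mods in ladders[donor]:
                if rng.random() < cfg.replicate_dropout_prob:
                    continue
                peptide = molecule.chain(core.chain_id).region(start, end)
                rows.append(
                    (
                        peptide,
                        mods,
                        [f"{cfg.molecule_name}|{core.chain_id}"],
                        False,
                        True,
                        core.core_id,
                    )
                )

            # background: substrings of the synthetic self proteome
            n_bg = cfg.background_peptides
            if n_bg:
                lengths = _sample_lengths(rng, cfg, n_bg)
                prot_idx = rng.integers(0, len(protein_seqs), size=n_bg)
                u = rng.random(n_bg)
                bg_peptides: list[str] = []
                for i in range(n_bg):
                    L = int(lengths[i])
                    seq = protein_seqs[int(prot_idx[i])]
                    while True:
                        start0 = int(u[i] * (len(seq) - L + 1))
                        pep = seq[start0 : start0 + L]
                        if pep not in chain_seqs[0] and pep not in chain_seqs[1]:
                            break
                        # therapeutic collision (vanishingly rare): redraw
                        seq = protein_seqs[int(rng.integers(0, len(protein_seqs)))]
                        u[i] = rng.random()
                    bg_peptides.append(pep)
                bg_mods = _background_mods(rng, cfg, bg_peptides)
                false_flags = rng.random(n_bg) < cfg.false_target_fraction
                for i, pep in enumerate(bg_peptides):
                    rows.append(
                        (
                            pep,
                            bg_mods[i],
                            [protein_names[int(prot_idx[i])]],
                            False,
                            not bool(false_flags[i]),
                            None,
                        )
                    )

            # reversed-sequence decoys
            n_targets = len(rows)
            n_decoys = int(round(cfg.decoy_fraction * n_targets / (1.0 - cfg.decoy_fraction)))
            if n_decoys and n_targets:
                src = rng.integers(0, n_targets, size=n_decoys)
                for i in src:
                    pep = rows[int(i)][0][::-1]
                    rows.append((pep, [], ["DECOY"], True, False, None))

            n_rows = len(rows)
            charges = rng.choice(charges_domain, size=n_rows, p=charge_p)
            z = rng.standard_normal(n_rows)
            xcorrs = np.empty(n_rows)
            for i, (pep, mods, prots, is_decoy, is_true, core_id) in enumerate(rows):
                if is_true and not is_decoy:
                    mu = cfg.true_xcorr_logmu[min(int(charges[i]), 4)]
                    xcorrs[i] = np.exp(mu + cfg.true_xcorr_logsigma * z[i])
                else:
                    xcorrs[i] = np.exp(
                        cfg.false_xcorr_logmu + cfg.false_xcorr_logsigma * z[i]
                    )

            records: list[PSMRecord] = []
            labels: list[tuple[bool, str | None]] = []
            for i, (pep, mods, prots, is_decoy, is_true, core_id) in enumerate(rows):
                rec = PSMRecord(
                    sample_id=sample_id,
                    donor_id=donor,
                    day=day,
                    analyst=analyst,
                    peptide=pep,
                    charge=int(charges[i]),
                    xcorr=float(xcorrs[i]),
                    mods=list(mods),
                    protein_ids=prots,
                    is_decoy=is_decoy,
                )
                records.append(rec)
                label = (is_true and not is_decoy, core_id)
                labels.append(label)
                label_by_id[id(rec)] = label
            samples[sample_id] = records
            row_labels[sample_id] = labels

    truth = PanelTruth(
        planted_cores=cores,
        presentation=presentation,
        ladder_peptides=ladder_peptides,
        row_labels=row_labels,
        mod_events=mod_events,
        _label_by_id=label_by_id,
    )
    return SimulatedPanel(
        config=cfg,
        molecule=molecule,
        background_proteome=background_proteome,
        donors=donors,
        samples=samples,
        sample_donor=sample_donor,
        truth=truth,
    )


@dataclass
class RecoveryMetrics:
    """How well the pipeline recovered the planted ground truth."""

    cluster_recovery: float  # recovered / presented-and-emitted (donor, core) pairs
    peptide_sensitivity: float  # accepted true therapeutic rows / emitted ones
    realized_fdr: float  # false rows among accepted, by ground truth
    n_presented: int
    n_recovered: int
    n_accepted: int


def truth_compare(
    panel: SimulatedPanel,
    accepted_records: Sequence[PSMRecord],
    clusters_by_donor: Mapping[str, Sequence[Cluster]],
) -> RecoveryMetrics:
    """Score a pipeline run on a simulated panel against the ground truth."""
    truth = panel.truth
    accepted_ids = {id(r) for r in accepted_records}
    for rec in accepted_records:
        if id(rec) not in truth._label_by_id:
            raise ConfigError("accepted record does not belong to this panel")

    n_accepted = len(accepted_records)
    n_false_accepted = sum(
        1 for rec in accepted_records if not truth.label_of(rec)[0]
    )
    realized_fdr = n_false_accepted / n_accepted if n_accepted else 0.0

    emitted_true = 0
    accepted_true_therapeutic = 0
    emitted_cores: set[tuple[str, str]] = set()
    for sid, records in panel.samples.items():
        donor = panel.sample_donor[sid]
        for rec, (is_true, core_id) in zip(records, truth.row_labels[sid]):
            if is_true and core_id is not None:
                emitted_true += 1
                emitted_cores.add((donor, core_id))
                if id(rec) in accepted_ids:
                    accepted_true_therapeutic += 1
    peptide_sensitivity = (
        accepted_true_therapeutic / emitted_true if emitted_true else 0.0
    )

    core_by_id = {c.core_id: c for c in truth.planted_cores}
    denominator_pairs = [
        pair for pair in truth.presented_pairs() if pair in emitted_cores
    ]
    n_recovered = 0
    for donor, core_id in denominator_pairs:
        core = core_by_id[core_id]
        clusters = clusters_by_donor.get(donor, [])
        if any(
            cl.chain_id == core.chain_id
            and interval_overlap(cl.core, core.interval) >= 1
            for cl in clusters
        ):
            n_recovered += 1
    n_presented = len(denominator_pairs)
    cluster_recovery = n_recovered / n_presented if n_presented else 1.0

    return RecoveryMetrics(
        cluster_recovery=cluster_recovery,
        peptide_sensitivity=peptide_sensitivity,
        realized_fdr=realized_fdr,
        n_presented=n_presented,
        n_recovered=n_recovered,
        n_accepted=n_accepted,
    )
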