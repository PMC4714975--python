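"""Synthetic IgH repertoires and barcoded paired-end sequencing runs.

The generator emulates the statistical structure the analysis assumes in
real data: V(D)J rearrangement with exonuclease trimming, P additions and
Tdt-dependent N additions (``n_insertion_rate=0`` reproduces the
N-free neonatal wave), Zipf-distributed clonal expansion, AID point
mutation biased to DGYW/WRCH hotspot contexts, class-switched constant
regions, and per-base sequencing error with a two-component quality model
(high ~Q35 for clean bases; error positions enriched for ~Q15 so the
quality-trimming rule has something real to do).

Amplicons span the full V (so the relatedness filter is exercisable),
the junction, J and the start of the constant region — as in the assay,
where reads cover CDR2 through CDR3 into the constant region. The reverse
read starts with the 6-nt sample barcode followed by the
reverse-complemented 3' end of the amplicon.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .barcodes import BarcodeSet
from .dna import BASES, revcomp, translate
from .junction import decompose_gap
from .reference import GermlineReference

SWITCHED_ISOTYPES = ("IgG1", "IgG3", "IgG2b", "IgG2c", "IgE", "IgA")


@dataclass
class SimulationParams:
    """Knobs of the repertoire/sequencing simulator.

    n_insertion_rate is the mean N length per junction (geometric law);
    0 disables N additions entirely, emulating the Tdt-negative neonatal
    wave. shm_rate is substitutions per base over the amplicon;
    hotspot_bias multiplies the relative mutation rate of positions lying
    in a DGYW/WRCH 4-mer context (total mutation load stays shm_rate per
    base). abundance_law is the Zipf exponent of the clone-size
    distribution, and total_reads the scale it is mapped onto.
    """

    n_clonotypes: int = 1000
    abundance_law: float = 1.2
    n_insertion_rate: float = 2.0
    shm_rate: float = 2e-3
    hotspot_bias: float = 4.0
    switch_prob: float = 0.05
    seq_error_rate: float = 3e-3
    read_length: int = 250
    seed: int = 0
    total_reads: int = 10_000
    switch_mutated_only: bool = False

    def __post_init__(self) -> None:
        for name in ("shm_rate", "switch_prob", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.abundance_law <= 0:
            raise ValueError("abundance_law must be > 0")
        if self.hotspot_bias < 1:
            raise ValueError("hotspot_bias must be >= 1")
        if self.n_insertion_rate < 0:
            raise ValueError("n_insertion_rate must be >= 0")
        if self.n_clonotypes < 1 or self.read_length < 50 or self.total_reads < 1:
            raise ValueError("invalid n_clonotypes/read_length/total_reads")


@dataclass
class TrueClonotype:
    """Ground truth for one simulated clonotype.

    Junction labels (deletions, N, P, d_id) follow the package's canonical
    template-first convention (see :mod:`ighrep.junction`); ``full_nt`` is
    the final transcript with mutations applied, reconstructible from the
    germline segments plus the stored junction fields and mutation list.
    """

    id: str
    v_id: str
    d_id: str | None
    j_id: str
    v_del: int
    d5_del: int
    d3_del: int
    j_del: int
    n1: str
    n2: str
    p1: str
    p2: str
    full_nt: str
    cdr3_start: int
    cdr3_end: int
    cdr3_nt: str
    cdr3_aa: str
    mutations: list[tuple[int, str, str]]
    isotype: str
    abundance: int = 1

    @property
    def n_total(self) -> int:
        return len(self.n1) + len(self.n2)


def _geometric_len(rng: np.random.Generator, mean: float) -> int:
    if mean <= 0:
        return 0
    return int(rng.geometric(1.0 / (1.0 + mean)) - 1)


def _trim_len(rng: np.random.Generator, cap: int) -> int:
    return min(int(rng.geometric(0.45) - 1), cap)


def hotspot_position_mask(seq: str) -> np.ndarray:
    """Boolean mask of positions covered by any DGYW/WRCH 4-mer.

    Vectorized equivalent of testing :func:`ighrep.dna.hotspot_class` at
    every position.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_ = {b: arr == ord(b) for b in "ACGT"}
    D = is_["A"] | is_["G"] | is_["T"]
    Y = is_["C"] | is_["T"]
    W = is_["A"] | is_["T"]
    R = is_["A"] | is_["G"]
    H = is_["T"] | is_["C"] | is_["A"]
    L = len(arr)
    hot = np.zeros(L, dtype=bool)
    if L >= 4:
        dgyw = D[:-3] & is_["G"][1:-2] & Y[2:-1] & W[3:]
        wrch = W[:-3] & R[1:-2] & is_["C"][2:-1] & H[3:]
        window = dgyw | wrch
        for off in range(4):  # a window at i covers positions i..i+3
            hot[off : off + window.size] |= window
    return hot


def _hotspot_weights(seq: str, bias: float) -> np.ndarray:
    w = np.ones(len(seq))
    w[hotspot_position_mask(seq)] = bias
    return w


def simulate_repertoire(
    params: SimulationParams,
    ref: GermlineReference,
    sample_id: str = "S1",
    rng: np.random.Generator | None = None,
) -> list[TrueClonotype]:
    """Draw ``params.n_clonotypes`` distinct clonotypes with abundances.

    Clone sizes follow a Zipf law with exponent ``params.abundance_law``
    scaled to ``params.total_reads`` (every clonotype keeps abundance >= 1).
    All CDR3s are generated in the V reading frame without stop codons;
    subsequent hotspot-biased mutation may render individual clonotypes
    unproductive, as in real repertoires.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    vs, ds, js, cs = ref.v_segments, ref.d_segments, ref.j_segments, ref.c_segments
    if not (vs and ds and js and cs):
        raise ValueError("reference must contain V, D, J and C segments")
    iso_by_id = {c.id: c for c in cs}
    switched = [i for i in SWITCHED_ISOTYPES if i in iso_by_id]

    clonotypes: list[TrueClonotype] = []
    seen: set[str] = set()
    attempts = 0
    while len(clonotypes) < params.n_clonotypes:
        attempts += 1
        if attempts > 50 * params.n_clonotypes:
            raise RuntimeError("clonotype rejection sampling failed to converge")
        v = vs[rng.integers(len(vs))]
        d = ds[rng.integers(len(ds))]
        j = js[rng.integers(len(js))]

        v_cap = len(v.sequence) - v.cdr3_mark - 1
        v_del = _trim_len(rng, min(5, v_cap))
        j_del = _trim_len(rng, min(5, j.cdr3_mark - 1))
        d5 = _trim_len(rng, len(d.sequence))
        d3 = _trim_len(rng, max(0, len(d.sequence) - d5))
        d_part = d.sequence[d5 : len(d.sequence) - d3]

        p2 = ""
        if v_del == 0 and rng.random() < 0.5:
            k = int(rng.integers(1, 3))
            p2 = revcomp(v.sequence[-k:])
        p1 = ""
        if j_del == 0 and rng.random() < 0.5:
            k = int(rng.integers(1, 3))
            p1 = revcomp(j.sequence[:k])
        n2 = "".join(rng.choice(list(BASES), _geometric_len(rng, params.n_insertion_rate)))
        n1 = "".join(rng.choice(list(BASES), _geometric_len(rng, params.n_insertion_rate)))

        gap = p2 + n2 + d_part + n1 + p1
        v_part = v.sequence[: len(v.sequence) - v_del]
        j_part = j.sequence[j_del:]
        cdr3_len = (len(v_part) - v.cdr3_mark) + len(gap) + (j.cdr3_mark - j_del)
        if cdr3_len % 3 != 0 or cdr3_len == 0:
            continue

        body = v_part + gap + j_part
        cdr3_start = v.cdr3_mark
        cdr3_end = cdr3_start + cdr3_len
        cdr3_nt = body[cdr3_start:cdr3_end]
        aa = translate(cdr3_nt)
        if "*" in aa:
            continue

        # canonical junction labels on the unmutated assembly
        v_lcp = 0
        vseq = v.sequence
        while (
            v_lcp < len(vseq)
            and v_lcp < len(body)
            and body[v_lcp] == vseq[v_lcp]
        ):
            v_lcp += 1
        v_del_obs = len(vseq) - v_lcp
        j_begin = len(v_part) + len(gap)
        j_del_obs = j_del
        while j_del_obs > 0 and j_begin > v_lcp and body[j_begin - 1] == j.sequence[j_del_obs - 1]:
            j_begin -= 1
            j_del_obs -= 1
        gap_obs = body[v_lcp:j_begin]
        decomp = decompose_gap(
            gap_obs, vseq, v_del_obs, j.sequence, j_del_obs, ds
        )

        # number of mutations is fixed before the isotype choice so that
        # switching can be conditioned on mutation status without biasing
        # the mutation load
        n_mut = (
            int(rng.binomial(len(body) + len(cs[0].sequence), params.shm_rate))
            if params.shm_rate > 0
            else 0
        )
        isotype = "IgM"
        u_switch = rng.random()
        if switched and u_switch < params.switch_prob:
            if n_mut > 0 or not params.switch_mutated_only:
                isotype = switched[rng.integers(len(switched))]
        c = iso_by_id[isotype]
        premut = body + c.sequence

        # hotspot-biased point mutation; total load stays shm_rate per base
        mutations: list[tuple[int, str, str]] = []
        seq = premut
        if n_mut:
            w = _hotspot_weights(premut, params.hotspot_bias)
            pos = rng.choice(
                len(premut), size=min(n_mut, len(premut)), replace=False,
                p=w / w.sum(),
            )
            s = list(premut)
            for p in sorted(int(x) for x in pos):
                old = s[p]
                new = str(rng.choice([b for b in BASES if b != old]))
                mutations.append((p, old, new))
                s[p] = new
            seq = "".join(s)

        if seq in seen:
            continue
        seen.add(seq)

        cdr3_nt_final = seq[cdr3_start:cdr3_end]
        aa_final = translate(cdr3_nt_final)
        clonotypes.append(
            TrueClonotype(
                id=f"{sample_id}.c{len(clonotypes):05d}",
                v_id=v.id,
                d_id=decomp.d_id,
                j_id=j.id,
                v_del=v_del_obs,
                d5_del=decomp.d5_del,
                d3_del=decomp.d3_del,
                j_del=j_del_obs,
                n1=decomp.n1,
                n2=decomp.n2,
                p1=decomp.p1,
                p2=decomp.p2,
                full_nt=seq,
                cdr3_start=cdr3_start,
                cdr3_end=cdr3_end,
                cdr3_nt=cdr3_nt_final,
                cdr3_aa="" if "*" in aa_final else aa_final,
                mutations=mutations,
                isotype=isotype,
            )
        )

    # Zipf clone sizes scaled to total_reads
    ranks = np.arange(1, len(clonotypes) + 1, dtype=float)
    weights = ranks ** (-params.abundance_law)
    weights /= weights.sum()
    sizes = np.maximum(1, np.round(weights * params.total_reads).astype(int))
    order = rng.permutation(len(clonotypes))
    for idx, clono in zip(order, clonotypes):
        clono.abundance = int(sizes[idx])
    return clonotypes


@dataclass
class RunFiles:
    fwd_fastq: Path
    rev_fastq: Path
    truth_reads: Path
    truth_clonotypes: Path


def _quality_for(
    rng: np.random.Generator, length: int, err_mask: np.ndarray
) -> np.ndarray:
    q = np.clip(np.rint(rng.normal(37, 2, length)), 30, 40).astype(int)
    if err_mask.any():
        idx = np.flatnonzero(err_mask)
        low = rng.random(idx.size) < 0.5
        q[idx[low]] = np.clip(
            np.rint(rng.normal(15, 2, low.sum())), 8, 19
        ).astype(int)
        q[idx[~low]] = np.clip(
            np.rint(rng.normal(25, 3, (~low).sum())), 21, 30
        ).astype(int)
    return q


def _inject_errors(
    rng: np.random.Generator, seq: str, rate: float
) -> tuple[str, np.ndarray]:
    mask = rng.random(len(seq)) < rate if rate > 0 else np.zeros(len(seq), bool)
    if mask.any():
        s = list(seq)
        for i in np.flatnonzero(mask):
            s[i] = str(rng.choice([b for b in BASES if b != s[i]]))
        seq = "".join(s)
    return seq, mask


def _open_out(path: Path):
    if str(path).endswith(".gz"):
        # fixed mtime keeps gzip output byte-identical across runs
        return gzip.GzipFile(path, "wb", mtime=0)
    return open(path, "wb")


def emit_run(
    repertoires: dict[str, list[TrueClonotype]],
    barcodes: BarcodeSet,
    params: SimulationParams,
    out_dir: str | Path,
    prefix: str = "run",
    min_overlap: int = 20,
) -> RunFiles:
    """Write a barcoded paired-end FASTQ run plus read/clonotype truth tables.

    The forward read covers the 5' of the amplicon; the reverse read is
    stored 5'->3' as sequenced: the sample barcode followed by the
    reverse complement of the amplicon 3' end. Refuses configurations
    whose mate overlap would fall below ``min_overlap`` (unmergeable by
    construction). Sequencing errors may hit barcode bases too — such
    reads end up unassigned at demultiplexing, as in a real run.
    """
    if len(barcodes) < len(repertoires):
        raise ValueError("need at least one barcode per sample")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = RunFiles(
        out_dir / f"{prefix}_R1.fastq",
        out_dir / f"{prefix}_R2.fastq",
        out_dir / f"{prefix}_truth_reads.tsv",
        out_dir / f"{prefix}_truth_clonotypes.tsv",
    )
    rng = np.random.default_rng([params.seed, 2_718_281])
    bc_len = barcodes.length
    rev_insert = params.read_length - bc_len

    with _open_out(files.fwd_fastq) as f1, _open_out(files.rev_fastq) as f2, open(
        files.truth_reads, "w"
    ) as ft, open(files.truth_clonotypes, "w") as fc:
        ft.write("read_id\tsample_id\tclonotype_id\n")
        fc.write(
            "sample_id\tclonotype_id\tv_call\td_call\tj_call\tisotype\tabundance\t"
            "cdr3_nt\tcdr3_aa\tv_del\td5_del\td3_del\tj_del\tn1_len\tn2_len\t"
            "n_total\tn_mutations\tfull_nt\n"
        )
        serial = 0
        for sample, barcode in zip(repertoires, barcodes):
            for clono in repertoires[sample]:
                amp = clono.full_nt
                if len(amp) < params.read_length:
                    raise ValueError("amplicon shorter than read length")
                overlap = params.read_length + rev_insert - len(amp)
                if overlap < min_overlap:
                    raise ValueError(
                        f"mate overlap {overlap} below required minimum {min_overlap}"
                    )
                fc.write(
                    "\t".join(
                        map(
                            str,
                            [
                                sample, clono.id, clono.v_id,
                                clono.d_id or "", clono.j_id, clono.isotype,
                                clono.abundance, clono.cdr3_nt, clono.cdr3_aa,
                                clono.v_del, clono.d5_del, clono.d3_del,
                                clono.j_del, len(clono.n1), len(clono.n2),
                                clono.n_total, len(clono.mutations), amp,
                            ],
                        )
                    )
                    + "\n"
                )
                fwd_t = amp[: params.read_length]
                rev_t = barcode + revcomp(amp[len(amp) - rev_insert :])
                for _ in range(clono.abundance):
                    rid = f"read{serial:07d}"
                    serial += 1
                    fwd, m1 = _inject_errors(rng, fwd_t, params.seq_error_rate)
                    rev, m2 = _inject_errors(rng, rev_t, params.seq_error_rate)
                    q1 = _quality_for(rng, len(fwd), m1)
                    q2 = _quality_for(rng, len(rev), m2)
                    f1.write(
                        f"@{rid}\n{fwd}\n+\n"
                        f"{''.join(chr(q + 33) for q in q1)}\n".encode()
                    )
                    f2.write(
                        f"@{rid}\n{rev}\n+\n"
                        f"{''.join(chr(q + 33) for q in q2)}\n".encode()
                    )
                    ft.write(f"{rid}\t{sample}\t{clono.id}\n")
    return files
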