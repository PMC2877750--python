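"""Per-CpG methylation calling from bisulfite amplicon reads.

Bisulfite treatment deaminates unmethylated cytosines to uracil (read as T
after PCR) while 5-methylcytosine is protected and stays C. On the top
strand of an amplicon this gives a simple readout: at a CpG cytosine, C
means methylated and T unmethylated; at every non-CpG cytosine the base
should read T, so the residual C fraction measures conversion (deamination)
failure and serves as the assay's QC metric.

Only the bisulfite top strand is modeled: amplicons are defined on one
strand, matching primer design for strand-specific bisulfite PCR. Reads may
be shorter than the amplicon and are placed by the best ungapped offset
under a bisulfite-aware match score; gapped alignment (e.g. pyrosequencing
homopolymer indels) is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, PreconditionError

__all__ = [
    "find_cpg_sites",
    "Amplicon",
    "ReadCall",
    "AmpliconCallTable",
    "call_read",
    "call_reads",
    "site_fractions",
    "deamination_efficiency",
    "compare_to_array",
]

METHYLATED = "M"
UNMETHYLATED = "U"
GAP = "."


def find_cpg_sites(sequence: str) -> list[int]:
    """0-based positions of the C of every CpG dinucleotide (top strand)."""
    seq = sequence.upper()
    return [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]


@dataclass(frozen=True)
class Amplicon:
    """A bisulfite PCR amplicon on the top strand.

    ``probe_links`` maps a CpG index (position in ``cpg_positions``) to the
    array probe interrogating that site, for sequencing-vs-array comparison.
    """

    name: str
    sequence: str
    cpg_positions: tuple[int, ...]
    probe_links: Mapping[int, str] = field(default_factory=dict)
    strand: str = "+"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        for pos in self.cpg_positions:
            if seq[pos : pos + 2] != "CG":
                raise InputError(
                    f"amplicon {self.name}: position {pos} is not the C of a CpG"
                )
        for idx in self.probe_links:
            if not 0 <= idx < len(self.cpg_positions):
                raise InputError(
                    f"amplicon {self.name}: probe link refers to CpG index {idx}, "
                    f"but only {len(self.cpg_positions)} CpGs exist"
                )

    @classmethod
    def from_sequence(
        cls,
        name: str,
        sequence: str,
        probe_links: Mapping[int, str] | None = None,
    ) -> "Amplicon":
        positions = tuple(find_cpg_sites(sequence))
        if not positions:
            raise InputError(f"amplicon {name} contains no CpG dinucleotide")
        return cls(name, sequence.upper(), positions, probe_links or {})

    @property
    def non_cpg_c_positions(self) -> list[int]:
        cpg = set(self.cpg_positions)
        return [
            i for i, base in enumerate(self.sequence) if base == "C" and i not in cpg
        ]


@dataclass
class ReadCall:
    read_id: str
    offset: int
    calls: list[str]
    converted: int
    unconverted: int
    rejected: str | None = None

    @property
    def conversion_total(self) -> int:
        return self.converted + self.unconverted


def _best_offset(read: str, reference: str) -> tuple[int, float]:
    """Best ungapped placement under bisulfite-aware scoring.

    A read base matches when identical to the reference, or when the
    reference has C and the read T (converted cytosine). Ties go to the
    smallest offset.
    """
    best_off, best_score = 0, -1
    for off in range(len(reference) - len(read) + 1):
        score = sum(
            r == q or (q == "C" and r == "T")
            for r, q in zip(read, reference[off : off + len(read)])
        )
        if score > best_score:
            best_off, best_score = off, score
    return best_off, best_score / len(read)


def call_read(read: str, amplicon: Amplicon, min_identity: float = 0.9) -> ReadCall:
    """Call per-CpG methylation on one read.

    At each covered CpG cytosine: C -> methylated, T -> unmethylated, any
    other base -> gap; uncovered CpGs are gaps. Non-CpG cytosines covered by
    the read are tallied as converted (T) or unconverted (C). Reads whose
    best placement falls below ``min_identity`` are rejected.
    """
    seq = str(read.seq).upper() if hasattr(read, "seq") else str(read).upper()
    read_id = getattr(read, "id", "read")
    ref = amplicon.sequence
    if len(seq) == 0:
        return ReadCall(read_id, 0, [GAP] * len(amplicon.cpg_positions), 0, 0,
                        rejected="empty read")
    if len(seq) > len(ref):
        return ReadCall(read_id, 0, [GAP] * len(amplicon.cpg_positions), 0, 0,
                        rejected="read longer than amplicon")
    offset, identity = _best_offset(seq, ref)
    if identity < min_identity:
        return ReadCall(
            read_id, offset, [GAP] * len(amplicon.cpg_positions), 0, 0,
            rejected=f"best identity {identity:.2f} below {min_identity:.2f}",
        )
    end = offset + len(seq)
    calls = []
    for pos in amplicon.cpg_positions:
        if offset <= pos < end:
            base = seq[pos - offset]
            calls.append(
                METHYLATED if base == "C" else UNMETHYLATED if base == "T" else GAP
            )
        else:
            calls.append(GAP)
    converted = unconverted = 0
    for pos in amplicon.non_cpg_c_positions:
        if offset <= pos < end:
            base = seq[pos - offset]
            if base == "T":
                converted += 1
            elif base == "C":
                unconverted += 1
    return ReadCall(read_id, offset, calls, converted, unconverted)


@dataclass
class AmpliconCallTable:
    """Per-read, per-CpG calls for one amplicon.

    ``calls`` is a reads x CpG-sites frame of 'M'/'U'/'.' with 1-based CpG
    coordinates as column labels; ``conversion`` holds per-read converted /
    unconverted counts at non-CpG cytosines.
    """

    amplicon: Amplicon
    calls: pd.DataFrame
    conversion: pd.DataFrame
    rejected: pd.DataFrame

    @property
    def n_reads(self) -> int:
        return len(self.calls)


def call_reads(
    reads: Sequence, amplicon: Amplicon, min_identity: float = 0.9
) -> AmpliconCallTable:
    results = [call_read(r, amplicon, min_identity) for r in reads]
    kept = [r for r in results if r.rejected is None]
    rejected = pd.DataFrame(
        [(r.read_id, r.rejected) for r in results if r.rejected is not None],
        columns=["read_id", "reason"],
    )
    columns = [pos + 1 for pos in amplicon.cpg_positions]  # 1-based for reports
    ids = [r.read_id for r in kept]
    calls = pd.DataFrame(
        [r.calls for r in kept], index=pd.Index(ids, name="read_id"), columns=columns
    )
    conversion = pd.DataFrame(
        {
            "converted": [r.converted for r in kept],
            "unconverted": [r.unconverted for r in kept],
        },
        index=pd.Index(ids, name="read_id"),
    )
    return AmpliconCallTable(amplicon, calls, conversion, rejected)


def site_fractions(table: AmpliconCallTable) -> pd.DataFrame:
    """Percent methylation and coverage per CpG site.

    Sites with zero coverage are reported with NaN percent (missing), never
    as 0% methylation.
    """
    records = []
    for col in table.calls.columns:
        col_calls = table.calls[col]
        n_meth = int((col_calls == METHYLATED).sum())
        n_unmeth = int((col_calls == UNMETHYLATED).sum())
        coverage = n_meth + n_unmeth
        pct = 100.0 * n_meth / coverage if coverage else float("nan")
        records.append((col, coverage, n_meth, n_unmeth, pct))
    return pd.DataFrame(
        records,
        columns=["position", "coverage", "n_methylated", "n_unmethylated",
                 "percent_methylated"],
    ).set_index("position")


@dataclass
class DeaminationResult:
    efficiency: float
    per_read: pd.Series
    qc_pass: bool
    threshold: float


def deamination_efficiency(
    table: AmpliconCallTable, threshold: float = 0.99
) -> DeaminationResult:
    """Conversion fraction at non-CpG cytosines, pooled over reads.

    The bisulfite assay's QC: efficiencies below ``threshold`` flag
    incomplete conversion, which would inflate apparent methylation.
    """
    conv = table.conversion["converted"].sum()
    unconv = table.conversion["unconverted"].sum()
    total = conv + unconv
    if total == 0:
        warnings.warn(
            "no non-CpG cytosine observations; deamination efficiency undefined",
            stacklevel=2,
        )
        return DeaminationResult(float("nan"), pd.Series(dtype=float), False, threshold)
    per_read_total = table.conversion.sum(axis=1)
    with np.errstate(invalid="ignore"):
        per_read = table.conversion["converted"] / per_read_total
    efficiency = conv / total
    return DeaminationResult(float(efficiency), per_read, efficiency >= threshold,
                             threshold)


def compare_to_array(
    fractions: pd.DataFrame,
    amplicon: Amplicon,
    group_beta: Mapping[str, float] | pd.Series,
    threshold: float = 0.2,
) -> pd.DataFrame:
    """Pair sequencing percent methylation with array group-mean beta.

    ``threshold`` is in beta units (default 0.2, the array's delta-beta
    convention); sites differing by more are flagged discordant. CpGs
    without a probe link are skipped.
    """
    if not amplicon.probe_links:
        raise PreconditionError(
            f"amplicon {amplicon.name} has no array probe links"
        )
    group_beta = pd.Series(group_beta, dtype=float)
    rows = []
    for cpg_idx, probe_id in sorted(amplicon.probe_links.items()):
        position = amplicon.cpg_positions[cpg_idx] + 1
        if probe_id not in group_beta.index:
            warnings.warn(f"probe {probe_id} absent from beta matrix; skipped",
                          stacklevel=2)
            continue
        seq_pct = float(fractions.loc[position, "percent_methylated"])
        array_pct = 100.0 * float(group_beta[probe_id])
        diff = seq_pct - array_pct
        rows.append(
            (position, probe_id, seq_pct, array_pct, diff,
             bool(abs(diff) <= 100.0 * threshold))
        )
    return pd.DataFrame(
        rows,
        columns=["position", "probe_id", "sequencing_percent", "array_percent",
                 "difference", "concordant"],
    )
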