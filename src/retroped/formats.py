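"""File-format emission and parsing helpers.

Conventions: BED is 0-based half-open; VCF is 1-based with symbolic
mobile-element ALT alleles (``<INS:ME:L1>`` etc.) and a per-sample FORMAT
field carrying the supporting read count.  FASTQ is Phred+33 (gzip
autodetected).  Config round-trips through YAML.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dna
from .calling import InsertionCall
from .reference import Reference
from .simconfig import SimConfig


def write_fasta(path, sequences: dict[str, np.ndarray], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, codes in sequences.items():
            fh.write(f">{name}\n")
            s = dna.decode(codes).decode()
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def read_fasta(path) -> dict[str, np.ndarray]:
    opener = gzip.open if str(path).endswith(".gz") else open
    out: dict[str, np.ndarray] = {}
    name = None
    chunks: list[str] = []
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    out[name] = dna.encode("".join(chunks))
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        out[name] = dna.encode("".join(chunks))
    return out


def write_bed(path, df: pd.DataFrame, extra_cols: list[str] | None = None) -> None:
    """BED with chrom/start/end/name plus optional extra columns."""
    cols = ["chrom", "start", "end", "name"] + (extra_cols or [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, extra_cols: list[str] | None = None) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "name"] + (extra_cols or [])
    df = pd.read_csv(path, sep="\t", header=None, names=cols,
                     dtype={"chrom": str})
    return df


def write_config(path, config: SimConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_yamlable(config.to_dict()), fh, sort_keys=True)


def read_config(path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    for key in ("tsd_range", "transduction_len_range", "insert_sizes",
                "germline_fraction_range", "somatic_fraction_range",
                "somatic_restricted_fraction_range"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    if "insertion_plan" in data:
        data["insertion_plan"] = [tuple(x) for x in data["insertion_plan"]]
    return SimConfig(**data)


def _yamlable(obj):
    if isinstance(obj, dict):
        return {k: _yamlable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yamlable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


VCF_HEADER = """\
##fileformat=VCFv4.2
##source=retroped
##ALT=<ID=INS:ME:L1,Description="L1 mobile element insertion">
##ALT=<ID=INS:ME:SINE,Description="SINE mobile element insertion">
##ALT=<ID=INS:ME:LTR,Description="LTR mobile element insertion">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">
##INFO=<ID=MEINFO,Number=4,Type=String,Description="Mobile element info: NAME,START,END,POLARITY">
##INFO=<ID=KNOWN,Number=0,Type=Flag,Description="Matches a known polymorphic insertion locus">
##INFO=<ID=FOUNDER,Number=0,Type=Flag,Description="Robust in every library of a founder animal">
##INFO=<ID=CHIMERA,Number=0,Type=Flag,Description="Chimera-suspect call">
##FORMAT=<ID=SR,Number=1,Type=Integer,Description="Supporting split reads">
"""

_ME_CLASS = {"L1_TF": "L1", "L1_GF": "L1", "L1_A": "L1",
             "B1": "SINE", "B2": "SINE", "IAP": "LTR", "ETn": "LTR"}


def write_vcf(path, calls: list[InsertionCall], reference: Reference,
              samples: list[str]) -> None:
    """Primary insertion calls as VCF 4.2 with symbolic ME ALT alleles."""
    lines = [VCF_HEADER]
    for chrom, length in reference.chrom_lengths().items():
        lines.append(f"##contig=<ID={chrom},length={length}>\n")
    safe = [s.replace(":", "_") for s in samples]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(safe) + "\n")
    ordered = sorted(calls, key=lambda c: (c.chrom, c.pos))
    for call in ordered:
        pos0 = call.pos
        ref_base = dna.decode(reference.seq(call.chrom, pos0 - 1, pos0)).decode() \
            if pos0 > 0 else "N"
        me = _ME_CLASS.get(call.subfamily, "L1")
        info = (f"SVTYPE=INS;MEINFO={call.subfamily},1,1,{call.te_orientation}")
        if call.known_polymorphic:
            info += ";KNOWN"
        if call.founder_polymorphic:
            info += ";FOUNDER"
        if call.chimera_suspect:
            info += ";CHIMERA"
        fields = [call.chrom, str(pos0), call.id, ref_base, f"<INS:ME:{me}>",
                  ".", "PASS", info, "SR"]
        fields += [str(call.support.get(s, 0)) for s in samples]
        lines.append("\t".join(fields) + "\n")
    with open(path, "w") as fh:
        fh.writelines(lines)


def write_truth_tables(outdir: Path, plan, truth: pd.DataFrame) -> None:
    rows = []
    for ev in plan:
        rows.append(dict(
            insertion_id=ev.id, chrom=ev.chrom, nick_pos=ev.nick_pos,
            pos_5p=ev.pos_5p, pos_3p=ev.pos_3p, strand=ev.strand,
            subfamily=ev.subfamily, origin_class=ev.origin_class,
            origin_animal=ev.origin_animal or "", tsd_len=ev.tsd_len,
            polyA_len=ev.polyA_len, n_monomers=ev.n_monomers,
            transduction_len=len(ev.transduction[0]) if ev.transduction else 0,
            donor=ev.transduction[1] if ev.transduction else ""))
    pd.DataFrame(rows).to_csv(outdir / "truth_insertions.tsv", sep="\t",
                              index=False)
    truth.to_csv(outdir / "truth_prevalence.tsv", sep="\t", index=False)


def write_qpcr_csv(path, measurements: list) -> None:
    """qPCR Ct table: sample, assay role (target/reference), replicate Cts."""
    rows = []
    for m in measurements:
        for role, cts in (("target", m.target_ct),
                          ("reference", m.reference_ct)):
            for i, ct in enumerate(cts, 1):
                rows.append(dict(sample=m.sample_id, role=role, replicate=i,
                                 ct="" if np.isnan(ct) else round(ct, 4)))
    pd.DataFrame(rows).to_csv(path, index=False)


def read_qpcr_csv(path) -> list:
    from .qpcr_sim import QpcrMeasurement, NO_AMPLIFICATION
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for sample, sub in df.groupby("sample", sort=False):
        cts = {"target": [], "reference": []}
        for r in sub.itertuples():
            ct = NO_AMPLIFICATION if r.ct == "" else float(r.ct)
            cts[r.role].append(ct)
        out.append(QpcrMeasurement(sample_id=str(sample),
                                   target_ct=cts["target"],
                                   reference_ct=cts["reference"]))
    return out


def write_pedigree(path, ped) -> None:
    rows = [dict(animal=a, sex=s, dam=d or "", sire=r or "", generation=g)
            for a, s, d, r, g in ped.animals]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
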