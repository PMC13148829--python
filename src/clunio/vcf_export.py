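"""Optional VCF v4.2 export of sampled genotypes (requires pysam).

Sites are synthetic biallelic SNVs on a single contig the length of the
simulated genome; REF/ALT alleles are placeholders (A/T) since the model
tracks presence of derived mutations, not nucleotide state.  The additive
phenotypic effect and origin generation of each mutation are carried in
INFO fields ``EFFECT`` and ``ORIGIN``.
"""

from __future__ import annotations

import numpy as np

from .results import GenotypeSample


def write_vcf(sample: GenotypeSample, path: str, genome_length: int = 1_000_000,
              contig: str = "1") -> None:
    """Write one genotype sample as an uncompressed VCF v4.2 file."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={genome_length}>")
    header.add_line('##INFO=<ID=EFFECT,Number=1,Type=Float,'
                    'Description="Additive effect on lunar emergence day">')
    header.add_line('##INFO=<ID=ORIGIN,Number=1,Type=Integer,'
                    'Description="Generation the mutation arose">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    n = sample.matrix.shape[0]
    for i in range(n):
        header.add_sample(f"ind{i}")

    order = np.argsort(sample.sites["position"].to_numpy(), kind="stable")
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for j in order:
            site = sample.sites.iloc[j]
            rec = vcf.new_record(
                contig=contig,
                start=int(site["position"]),
                stop=int(site["position"]) + 1,
                alleles=("A", "T"),
                id=f"mut{int(site['id'])}",
            )
            rec.info["EFFECT"] = float(site["effect"])
            rec.info["ORIGIN"] = int(site["origin_generation"])
            for i in range(n):
                copies = int(sample.matrix[i, j])
                rec.samples[i]["GT"] = ((0, 0), (0, 1), (1, 1))[copies]
            vcf.write(rec)
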