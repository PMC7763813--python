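import numpy as np
import pytest

from melpanel.fixtures import build_reference_cohort, load_fixtures, load_panel_models


@pytest.fixture(scope="session")
def models():
    return load_panel_models()


@pytest.fixture(scope="session")
def cdkn2a(models):
    return models["CDKN2A"]


@pytest.fixture(scope="session")
def bundle():
    return load_fixtures()


@pytest.fixture(scope="session")
def reference_cohort():
    from melpanel.cohort import apply_panel, triage

    patients = build_reference_cohort(seed=0)
    for p in patients:
        triage(p)
        apply_panel(p)
    return patients


def random_exonic_variants(model, isoform, rng: np.random.Generator, n: int):
    """Random exonic SNVs/indels that stay inside one exon and one region.

    Yields VariantRecords (coding-strand alleles, anchor convention of the
    package).  Deletions/insertions avoid CDS/UTR boundaries and exon edges
    so the brute-force oracle's assumptions hold.
    """
    from melpanel.consequence import VariantRecord
    from melpanel.transcript import GenomicPosition, reverse_complement

    locus = model.reference
    out = []
    attempts = 0
    while len(out) < n and attempts < n * 60:
        attempts += 1
        exon = isoform.exons[int(rng.integers(len(isoform.exons)))]
        kind = ["snv", "del", "ins"][int(rng.integers(3))]
        gpos = int(rng.integers(exon.start, exon.end + 1))
        t = isoform.genomic_to_transcript(gpos)
        if t is None:
            continue
        cs, ce = isoform.cds_start, isoform.cds_end
        step = 1 if isoform.strand == "+" else -1

        def coding_base(g):
            b = locus.base(g)
            return b if isoform.strand == "+" else reverse_complement(b)

        if kind == "snv":
            ref = coding_base(gpos)
            alt = "ACGT".replace(ref, "")[int(rng.integers(3))]
            out.append(
                VariantRecord("TOY", GenomicPosition(locus.chrom or "chrT", gpos),
                              ref, alt)
            )
        elif kind == "del":
            L = int(rng.integers(1, 7))
            # keep the deleted run inside the exon and inside one region
            g_last = gpos + step * (L - 1)
            if not (exon.start <= g_last <= exon.end):
                continue
            t_last = t + L - 1
            if (t < cs) != (t_last < cs) or (t > ce) != (t_last > ce):
                continue
            if t <= ce and t_last >= ce - 0:  # do not chew through the stop
                if t <= ce and t_last >= ce:
                    continue
            ref = "".join(coding_base(gpos + step * i) for i in range(L))
            out.append(
                VariantRecord("TOY", GenomicPosition(locus.chrom or "chrT", gpos),
                              ref, "")
            )
        else:
            # anchor strictly inside the exon (next coding base in same exon)
            g_next = gpos + step
            if not (exon.start <= g_next <= exon.end):
                continue
            if t == cs - 1 or t == ce - 1:  # skip region boundaries
                continue
            L = int(rng.integers(1, 6))
            alt = "".join("ACGT"[int(rng.integers(4))] for _ in range(L))
            out.append(
                VariantRecord("TOY", GenomicPosition(locus.chrom or "chrT", gpos),
                              "", alt)
            )
    return out
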