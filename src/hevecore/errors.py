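"""Exceptions and warnings shared across the package."""


class HevecoreError(Exception):
    """Base class for all package errors."""


class MultiallelicSiteError(HevecoreError):
    """A VCF record carries more than one ALT allele; only biallelic SNPs are supported."""


class MissingGenotypeFormatError(HevecoreError):
    """A VCF lacks the GT FORMAT field required to code genotypes."""


class NonDiploidCallError(HevecoreError):
    """A genotype call is not diploid."""


class AllSamplesRemovedError(HevecoreError):
    """A sample filter removed every sample."""


class AllLociRemovedError(HevecoreError):
    """A variant filter removed every locus."""


class AllMissingColumnError(HevecoreError):
    """Allele frequencies are undefined for a column with no called genotypes."""


class ZeroSharedLociError(HevecoreError):
    """A sample pair shares no called loci, so their distance is undefined."""


class DegenerateTreeWarning(UserWarning):
    """All internal branches have zero length; group assignment is uninformative."""


class LowSampleWarning(UserWarning):
    """A population summary was computed on fewer than two samples."""
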