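# CRISPR-Cas presence call. A genome is CRISPR-positive iff at least one
# record matches the cas gene family or a CRISPR-associated product.
# Regulators of the system (LexA family) are reported as auxiliary
# evidence but are never sufficient on their own.
name: crispr_cas
core_symbol_prefixes: [cas]
core_keywords: ["crispr associated"]
auxiliary_keywords: ["lexa family transcriptional regulator"]
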