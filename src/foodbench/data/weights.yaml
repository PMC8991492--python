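# Illustrative default domain weights (uniform per industry).  The
# operational weight sets are deployment configuration; replace this
# file or pass --weights to use study-specific values.
weights:
  manufacturer:
    corporate_strategy: 0.16666666666666666
    product_formulation: 0.16666666666666666
    nutrition_labelling: 0.16666666666666666
    promotion: 0.16666666666666666
    accessibility: 0.16666666666666666
    relationships: 0.1666666666666667
  supermarket:
    corporate_strategy: 0.16666666666666666
    product_formulation: 0.16666666666666666
    nutrition_labelling: 0.16666666666666666
    promotion: 0.16666666666666666
    accessibility: 0.16666666666666666
    relationships: 0.1666666666666667
  quick_service:
    corporate_strategy: 0.16666666666666666
    product_formulation: 0.16666666666666666
    nutrition_labelling: 0.16666666666666666
    promotion: 0.16666666666666666
    accessibility: 0.16666666666666666
    relationships: 0.1666666666666667
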