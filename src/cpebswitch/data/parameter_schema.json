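{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "cpebswitch ParameterSet",
  "description": "Rate constants and free concentrations of the CPEB1-alphaCaMKII polyadenylation loop. All values are finite and non-negative; reduced-model use additionally requires lambda1 == lambda2.",
  "type": "object",
  "additionalProperties": false,
  "properties": {
    "k1":      {"type": "number", "minimum": 0, "description": "X + X_P association into the autophosphorylation complex C1", "unit": "uM^-1 s^-1"},
    "k2":      {"type": "number", "minimum": 0, "description": "C1 dissociation", "unit": "s^-1"},
    "k3":      {"type": "number", "minimum": 0, "description": "C1 catalysis: C1 -> 2 X_P (autophosphorylation)", "unit": "s^-1"},
    "k4":      {"type": "number", "minimum": 0, "description": "X_P dephosphorylation by the phosphatase pool", "unit": "uM^-1 s^-1"},
    "k5":      {"type": "number", "minimum": 0, "description": "Y + X_P association into C2 (CPEB1 activation)", "unit": "uM^-1 s^-1"},
    "k55":     {"type": "number", "minimum": 0, "description": "C2 dissociation", "unit": "s^-1"},
    "k6":      {"type": "number", "minimum": 0, "description": "C2 catalysis: C2 -> Y_P + X_P", "unit": "s^-1"},
    "k7":      {"type": "number", "minimum": 0, "description": "Y_P dephosphorylation by the phosphatase pool", "unit": "uM^-1 s^-1"},
    "k8":      {"type": "number", "minimum": 0, "description": "Y_P + T association into the translation complex C3", "unit": "uM^-1 s^-1"},
    "k88":     {"type": "number", "minimum": 0, "description": "C3 dissociation", "unit": "s^-1"},
    "k9":      {"type": "number", "minimum": 0, "description": "C3 catalysis: synthesis of new inactive X", "unit": "s^-1"},
    "k10":     {"type": "number", "minimum": 0, "description": "Ca4CaM activation of X", "unit": "uM^-1 s^-1"},
    "k1010":   {"type": "number", "minimum": 0, "description": "reversal of Ca4CaM activation", "unit": "s^-1"},
    "lambda1": {"type": "number", "minimum": 0, "description": "degradation rate of free X_P (relaxation toward XPbasal)", "unit": "s^-1"},
    "lambda2": {"type": "number", "minimum": 0, "description": "degradation rate of free X (relaxation toward Xbasal)", "unit": "s^-1"},
    "P":       {"type": "number", "minimum": 0, "description": "phosphatase pool concentration", "unit": "uM"},
    "T":       {"type": "number", "minimum": 0, "description": "translation-machinery pool concentration", "unit": "uM"},
    "YT":      {"type": "number", "minimum": 0, "description": "total CPEB1 concentration", "unit": "uM"},
    "U_basal": {"type": "number", "minimum": 0, "description": "resting Ca4CaM concentration", "unit": "uM"},
    "Xbasal":  {"type": "number", "minimum": 0, "description": "basal inactive-kinase concentration", "unit": "uM"},
    "XPbasal": {"type": "number", "minimum": 0, "description": "basal phospho-kinase concentration", "unit": "uM"}
  },
  "required": []
}
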