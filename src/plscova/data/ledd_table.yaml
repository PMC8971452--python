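# Levodopa-equivalent daily dose conversion table.
# Each entry maps a drug-name keyword (case-insensitive substring match)
# to either a multiplicative factor on (dose x frequency), or — for COMT
# inhibitors — a multiplier applied to the subject's concurrent levodopa
# equivalents. Values follow the widely used published conversion factors;
# the whole table is user-overridable.
drugs:
  levodopa:            {factor: 1.0,  unit: mg}
  levodopa_cr:         {factor: 0.75, unit: mg, keywords: ["controlled release", "cr levodopa", "rytary"]}
  pramipexole:         {factor: 100.0, unit: mg}
  ropinirole:          {factor: 20.0,  unit: mg}
  rotigotine:          {factor: 30.0,  unit: mg}
  rasagiline:          {factor: 100.0, unit: mg}
  selegiline:          {factor: 10.0,  unit: mg}
  amantadine:          {factor: 1.0,   unit: mg}
  apomorphine:         {factor: 10.0,  unit: mg}
comt_inhibitors:
  entacapone:          {levodopa_multiplier: 1.33}
  tolcapone:           {levodopa_multiplier: 1.5}
  opicapone:           {levodopa_multiplier: 1.5}
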