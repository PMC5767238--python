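# Default content-unit checklist for Cookie Theft picture descriptions.
#
# Each unit maps to trigger patterns over the non-maze lemma sequence; a
# pattern is either a single lemma or a short multi-word lemma sequence that
# must occur contiguously.  A unit is scored at most once per sample.  The
# checklist follows the conventional scene inventory (people, objects,
# places, actions) used in picture-description scoring; it is configuration,
# not code, and can be replaced with any YAML file of the same shape.
units:
  boy: [boy, son, brother]
  girl: [girl, daughter, sister]
  woman: [woman, mother, lady]
  kitchen: [kitchen]
  exterior: [outside, garden, yard, [out, the, window]]
  cookie: [cookie, cookies, biscuit]
  jar: [jar]
  stool: [stool]
  sink: [sink]
  plate: [plate]
  dishcloth: [dishcloth, towel, rag]
  water: [water]
  window: [window]
  cupboard: [cupboard, cabinet, shelf]
  dishes: [dish, dishes]
  curtains: [curtain, curtains]
  boy_taking_cookie: [steal, stealing, [take, cookie], [get, cookie]]
  stool_falling: [fall, falling, tip, wobble, [lose, balance]]
  woman_drying: [dry, drying, wipe, [wash, dish]]
  water_overflowing: [overflow, overflowing, spill, [run, over]]
  girl_asking: [ask, asking, request, [want, cookie]]
  girl_reaching: [reach, reaching]
  woman_unconcerned: [unaware, daydream, daydreaming, oblivious, [not, notice]]
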