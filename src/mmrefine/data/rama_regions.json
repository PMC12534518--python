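{
  "_comment": "Coarse polygonal phi/psi regions for a simplified Ramachandran classifier (not a Z-score). Polygons are [phi, psi] vertex lists in degrees; a residue is favored/allowed if its point falls in any polygon of that class. Classes: general, gly, pro, prepro.",
  "general": {
    "favored": [
      [[-160, -80], [-160, 10], [-45, 10], [-45, -80]],
      [[-180, 75], [-180, 180], [-45, 180], [-45, 75]],
      [[-180, -180], [-180, -160], [-45, -160], [-45, -180]]
    ],
    "allowed": [
      [[-180, -100], [-180, 45], [-30, 45], [-30, -100]],
      [[-180, 45], [-180, 180], [-30, 180], [-30, 45]],
      [[-180, -180], [-180, -140], [-30, -140], [-30, -180]],
      [[30, -10], [30, 90], [100, 90], [100, -10]]
    ]
  },
  "gly": {
    "favored": [
      [[-160, -80], [-160, 10], [-45, 10], [-45, -80]],
      [[-180, 75], [-180, 180], [-45, 180], [-45, 75]],
      [[-180, -180], [-180, -160], [-45, -160], [-45, -180]],
      [[45, -10], [45, 80], [160, 80], [160, -10]],
      [[45, 150], [45, 180], [180, 180], [180, 150]]
    ],
    "allowed": [
      [[-180, -180], [-180, 180], [-30, 180], [-30, -180]],
      [[30, -60], [30, 100], [180, 100], [180, -60]],
      [[30, 120], [30, 180], [180, 180], [180, 120]],
      [[30, -180], [30, -120], [180, -120], [180, -180]]
    ]
  },
  "pro": {
    "favored": [
      [[-100, -60], [-100, 10], [-40, 10], [-40, -60]],
      [[-100, 110], [-100, 180], [-40, 180], [-40, 110]]
    ],
    "allowed": [
      [[-120, -80], [-120, 60], [-30, 60], [-30, -80]],
      [[-120, 60], [-120, 180], [-30, 180], [-30, 60]]
    ]
  },
  "prepro": {
    "favored": [
      [[-160, -60], [-160, 10], [-60, 10], [-60, -60]],
      [[-180, 75], [-180, 180], [-60, 180], [-60, 75]],
      [[-180, -180], [-180, -160], [-60, -160], [-60, -180]]
    ],
    "allowed": [
      [[-180, -100], [-180, 180], [-40, 180], [-40, -100]],
      [[-180, -180], [-180, -140], [-40, -140], [-40, -180]],
      [[30, 20], [30, 90], [90, 90], [90, 20]]
    ]
  }
}
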