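{
  "_comment": "Odds ratios [OR, CI low, CI high] and heterogeneity p-values as printed (2 decimals) in the source publication's association tables; used only for reproduction diffs, never as inputs to any computation.",
  "rs861539": {
    "per_study": {
      "Auranen": {
        "homozygote": [0.99, 0.83, 1.18],
        "heterozygote": [0.99, 0.88, 1.12],
        "dominant": [0.99, 0.88, 1.11],
        "recessive": [0.99, 0.84, 1.17]
      },
      "Beesley": {
        "homozygote": [0.93, 0.67, 1.27],
        "heterozygote": [0.96, 0.77, 1.19],
        "dominant": [0.95, 0.77, 1.17],
        "recessive": [0.95, 0.71, 1.27]
      },
      "Quaye": {
        "homozygote": [0.89, 0.72, 1.11],
        "heterozygote": [0.92, 0.79, 1.07],
        "dominant": [0.91, 0.79, 1.05],
        "recessive": [0.93, 0.76, 1.14]
      },
      "Webb": {
        "homozygote": [0.97, 0.74, 1.28],
        "heterozygote": [0.91, 0.75, 1.10],
        "dominant": [0.92, 0.77, 1.10],
        "recessive": [1.02, 0.79, 1.32]
      }
    },
    "pooled": {
      "homozygote": [0.95, 0.85, 1.06],
      "heterozygote": [0.95, 0.88, 1.03],
      "dominant": [0.95, 0.88, 1.02],
      "recessive": [0.97, 0.88, 1.08]
    },
    "heterogeneity_p": {
      "homozygote": 0.91,
      "heterozygote": 0.88,
      "dominant": 0.82,
      "recessive": 0.77
    }
  },
  "rs1799794": {
    "per_study": {
      "Auranen": {
        "homozygote": [0.72, 0.52, 1.00],
        "heterozygote": [1.11, 0.98, 1.26],
        "dominant": [1.07, 0.95, 1.20],
        "recessive": [0.69, 0.50, 0.96]
      },
      "Quaye": {
        "homozygote": [0.67, 0.45, 0.99],
        "heterozygote": [1.09, 0.94, 1.25],
        "dominant": [1.04, 0.91, 1.19],
        "recessive": [0.65, 0.44, 0.96]
      }
    },
    "pooled": {
      "homozygote": [0.70, 0.54, 0.90],
      "heterozygote": [1.10, 1.00, 1.21],
      "dominant": [1.06, 0.96, 1.15],
      "recessive": [0.67, 0.52, 0.87]
    },
    "heterogeneity_p": {
      "homozygote": 0.77,
      "heterozygote": 0.83,
      "dominant": 0.78,
      "recessive": 0.80
    }
  },
  "rs1799796": {
    "per_study": {
      "Auranen": {
        "homozygote": [1.07, 0.89, 1.29],
        "heterozygote": [0.89, 0.79, 1.01],
        "dominant": [0.93, 0.83, 1.04],
        "recessive": [1.13, 0.95, 1.35]
      },
      "Quaye": {
        "homozygote": [1.08, 0.87, 1.33],
        "heterozygote": [0.93, 0.81, 1.07],
        "dominant": [0.96, 0.84, 1.09],
        "recessive": [1.11, 0.91, 1.37]
      }
    },
    "pooled": {
      "homozygote": [1.07, 0.93, 1.24],
      "heterozygote": [0.91, 0.83, 0.99],
      "dominant": [0.94, 0.86, 1.03],
      "recessive": [1.13, 0.98, 1.29]
    },
    "heterogeneity_p": {
      "homozygote": 0.97,
      "heterozygote": 0.65,
      "dominant": 0.69,
      "recessive": 0.90
    }
  }
}
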