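tissue,freq_MHz,ratio_eps,ratio_sigma,source
skin,297,1.20,1.45,synthetic default: water-content-driven newborn/adult ratio (user-replaceable)
fat,297,1.90,2.40,synthetic default: water-content-driven newborn/adult ratio (user-replaceable)
muscle,297,1.10,1.25,synthetic default: water-content-driven newborn/adult ratio (user-replaceable)
bone,297,1.60,2.20,synthetic default: water-content-driven newborn/adult ratio (user-replaceable)
cartilage,297,1.15,1.30,synthetic default: water-content-driven newborn/adult ratio (user-replaceable)
brain,297,1.15,1.30,synthetic default: water-content-driven newborn/adult ratio (user-replaceable)
csf,297,1.00,1.00,synthetic default: CSF already near pure water
blood,297,1.05,1.10,synthetic default: water-content-driven newborn/adult ratio (user-replaceable)
heart,297,1.10,1.25,synthetic default: water-content-driven newborn/adult ratio (user-replaceable)
lung,297,1.10,1.20,synthetic default: water-content-driven newborn/adult ratio (user-replaceable)
liver,297,1.15,1.30,synthetic default: water-content-driven newborn/adult ratio (user-replaceable)
stomach,297,1.10,1.20,synthetic default: water-content-driven newborn/adult ratio (user-replaceable)
connective,297,1.30,1.60,synthetic default: water-content-driven newborn/adult ratio (user-replaceable)
blanket,297,1.00,1.00,insulation layer: not biological tissue
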