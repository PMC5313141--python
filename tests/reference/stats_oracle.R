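# Independent reference for the cohort statistics: one-way ANOVA,
# Tukey HSD and paired t-tests computed by base R on a long-format CSV
# with columns fixture, group, x, y.  Emits JSON keyed by fixture id.
#
# Usage: Rscript stats_oracle.R <input.csv> <output.json>

suppressMessages(library(jsonlite))

args <- commandArgs(trailingOnly = TRUE)
df <- read.csv(args[1], stringsAsFactors = FALSE)

out <- list()
for (f in unique(df$fixture)) {
  d <- df[df$fixture == f, ]
  d$group <- factor(d$group)
  fit <- aov(x ~ group, data = d)
  s <- summary(fit)[[1]]
  tk <- TukeyHSD(fit)$group
  paired <- list()
  for (g in levels(d$group)) {
    dd <- d[d$group == g, ]
    tt <- t.test(dd$x, dd$y, paired = TRUE)
    paired[[g]] <- list(t = unname(tt$statistic), p = tt$p.value)
  }
  out[[as.character(f)]] <- list(
    F = s$`F value`[1],
    p = s$`Pr(>F)`[1],
    tukey_pairs = rownames(tk),
    tukey_p = tk[, "p adj"],
    paired = paired
  )
}

writeLines(toJSON(out, digits = I(17), auto_unbox = TRUE), args[2])
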