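#!/usr/bin/env Rscript
# Batch runner for mixed-effects models.
# Usage: Rscript lme4_runner.R jobs.json out.json
# jobs.json: {"jobs": [{"name": ..., "data": csv-path, "formula": ...,
#                       "family": "binomial"|"gaussian", "reml": bool}]}
# Writes one JSON object keyed by job name with coefficient tables,
# random-effect SDs, log-likelihood and convergence information.

suppressMessages({
  library(lme4)
  library(jsonlite)
})

args <- commandArgs(trailingOnly = TRUE)
jobs <- fromJSON(args[[1]], simplifyVector = FALSE)$jobs
out <- list()

for (job in jobs) {
  d <- read.csv(job$data)
  f <- as.formula(job$formula)
  res <- tryCatch({
    if (job$family == "binomial") {
      m <- glmer(f, data = d, family = binomial)
      co <- summary(m)$coefficients
      stat <- co[, "z value"]
      p <- co[, "Pr(>|z|)"]
    } else {
      reml <- isTRUE(job$reml)
      m <- lmer(f, data = d, REML = reml)
      co <- summary(m)$coefficients
      stat <- co[, "t value"]
      p <- 2 * pnorm(-abs(stat))  # Wald t-as-z
    }
    vc <- as.data.frame(VarCorr(m))
    msgs <- unlist(m@optinfo$conv$lme4$messages)
    list(
      converged = is.null(msgs),
      messages = if (is.null(msgs)) list() else as.list(msgs),
      terms = rownames(co),
      estimate = unname(co[, "Estimate"]),
      se = unname(co[, "Std. Error"]),
      statistic = unname(stat),
      p = unname(p),
      loglik = as.numeric(logLik(m)),
      df = attr(logLik(m), "df"),
      nobs = nobs(m),
      vc_group = paste(vc$grp, vc$var1, sep = ":"),
      vc_sd = vc$sdcor
    )
  }, error = function(e) list(converged = FALSE, error = conditionMessage(e)))
  out[[job$name]] <- res
}

writeLines(toJSON(out, auto_unbox = TRUE, digits = 12, null = "null"), args[[2]])
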